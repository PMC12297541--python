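"""Incidence counting across studies and the Chao2 species-richness estimator.

A repertoire spread over several independent studies can be treated like an
ecological survey over sampling units: every unique paired sequence is a
"species", and each study either detects it or not. Chao2 extrapolates the
total richness from the counts of sequences seen in exactly one study (q1)
and exactly two studies (q2):

    S_chao2 = S_observed + q1^2 / (2 q2)

with the bias-corrected fallback S_observed + q1 (q1 - 1) / 2 when q2 = 0.
Keys are the concatenated heavy and light variable-region sequences
(nucleotide or amino-acid), separated by a character outside both alphabets.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DataError, EmptyResultError
from .io_formats import PairedDataset

#: separator between the concatenated heavy and light sequences; '|' occurs
#: in neither the nucleotide nor the amino-acid alphabet, so concatenated
#: keys are unambiguous.
KEY_SEPARATOR = "|"

KEY_MODES = ("nucleotide", "amino_acid")


@dataclass(frozen=True)
class IncidenceSummary:
    """Incidence counts across studies for the Chao2 estimator."""

    s_observed: int
    q1: int
    q2: int
    n_studies: int
    key_mode: str

    def __post_init__(self) -> None:
        if min(self.s_observed, self.q1, self.q2, self.n_studies) < 0:
            raise DataError("incidence counts must be non-negative")
        if self.q1 + self.q2 > self.s_observed:
            raise DataError("q1 + q2 cannot exceed s_observed")
        if self.n_studies == 1 and self.q2 != 0:
            raise DataError("q2 must be 0 when only one study is present")


@dataclass(frozen=True)
class RichnessEstimate:
    """A Chao2 estimate; ``corrected`` flags the q2 = 0 bias-corrected form."""

    estimate: float
    corrected: bool
    inputs: IncidenceSummary


def pair_key(record, key_mode: str = "nucleotide") -> str:
    """Concatenated H+L sequence key for one record."""
    if key_mode == "nucleotide":
        h, l = record.heavy.sequence_nt, record.light.sequence_nt
    elif key_mode == "amino_acid":
        h, l = record.heavy.sequence_aa, record.light.sequence_aa
    else:
        raise DataError(f"key_mode must be one of {KEY_MODES}, got {key_mode!r}")
    if not h or not l:
        raise DataError(
            f"record ({record.study_id}, {record.cell_id}) lacks a sequence for "
            f"key_mode={key_mode}"
        )
    return h + KEY_SEPARATOR + l


def incidence_counts(dataset: PairedDataset, key_mode: str = "nucleotide") -> IncidenceSummary:
    """Count in how many studies each unique paired sequence occurs.

    Incidence, not abundance: a key occurring many times within one study
    counts as present in that study once.
    """
    if not len(dataset):
        raise EmptyResultError("empty dataset")
    studies_by_key: dict[str, set[str]] = {}
    all_studies: set[str] = set()
    for rec in dataset:
        key = pair_key(rec, key_mode)
        studies_by_key.setdefault(key, set()).add(rec.study_id)
        all_studies.add(rec.study_id)
    return summarize_incidence(
        {k: v for k, v in studies_by_key.items()}, n_studies=len(all_studies), key_mode=key_mode
    )


def summarize_incidence(
    studies_by_key: dict[str, set[str]], n_studies: int, key_mode: str = "nucleotide"
) -> IncidenceSummary:
    """Build an IncidenceSummary from a key -> set-of-studies mapping."""
    q1 = sum(1 for s in studies_by_key.values() if len(s) == 1)
    q2 = sum(1 for s in studies_by_key.values() if len(s) == 2)
    return IncidenceSummary(
        s_observed=len(studies_by_key), q1=q1, q2=q2, n_studies=n_studies, key_mode=key_mode
    )


def incidence_from_study_sets(
    study_sets: dict[str, set[str]], key_mode: str = "nucleotide"
) -> IncidenceSummary:
    """Incidence summary from a study -> set-of-keys mapping (simulator output)."""
    by_key: dict[str, set[str]] = {}
    for study, keys in study_sets.items():
        for key in keys:
            by_key.setdefault(key, set()).add(study)
    return summarize_incidence(by_key, n_studies=len(study_sets), key_mode=key_mode)


def chao2(summary: IncidenceSummary) -> RichnessEstimate:
    """Chao2 richness estimate from incidence counts.

    Uses the classic form S + q1^2/(2 q2); when q2 = 0 falls back to the
    standard bias-corrected form S + q1 (q1 - 1)/2 and flags it.
    """
    if summary.q2 > 0:
        estimate = summary.s_observed + summary.q1**2 / (2 * summary.q2)
        corrected = False
    else:
        estimate = summary.s_observed + summary.q1 * (summary.q1 - 1) / 2
        corrected = True
    return RichnessEstimate(estimate=float(estimate), corrected=corrected, inputs=summary)
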