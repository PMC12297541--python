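"""Amino-acid distributions at IMGT positions and their comparison.

Two datasets (or the observed repertoire and a random-pairing null) are
compared position by position through

* the Total Variation Distance between per-position amino-acid proportions,

      D = 1/2 * sum_aa | P_ds1(aa) - P_ds2(aa) |,

  a number in [0, 1] (0 = identical distributions, 1 = disjoint support);
* a chi-square goodness-of-fit test with small-count binning: symbols with
  fewer than 5 observed counts in the compared dataset are pooled into an
  "other" category (expected counts pooled in parallel), then compared to
  expectations formed from the reference proportions;
* joint amino-acid-pair distributions over an (H position, L position) pair,
  set against the distribution expected under random H/L pairing — either
  the analytic product of the marginals or a seeded permutation of light
  chains across cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import chisquare

from .errors import DataError, EmptyResultError, TestNotApplicableError
from .io_formats import PairedDataset

OTHER = "other"


@dataclass(frozen=True)
class AADistribution:
    """Amino-acid counts and proportions at one IMGT position of one chain type."""

    position: str
    chain_type: str
    counts: Mapping[str, int]
    n: int

    @property
    def proportions(self) -> dict[str, float]:
        return {aa: c / self.n for aa, c in self.counts.items()}

    def __post_init__(self) -> None:
        if self.n != sum(self.counts.values()):
            raise DataError("n must equal the sum of counts")
        if self.n <= 0:
            raise EmptyResultError(f"empty distribution at {self.chain_type}:{self.position}")


@dataclass(frozen=True)
class PairAADistribution:
    """Joint distribution of amino-acid pairs at an (H position, L position) pair."""

    h_position: str
    l_position: str
    joint: Mapping[tuple[str, str], float]
    n: int

    def __post_init__(self) -> None:
        total = sum(self.joint.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"joint proportions sum to {total}, not 1")


def _chain(record, chain_type: str):
    if chain_type == "H":
        return record.heavy
    if chain_type == "L":
        return record.light
    raise DataError("chain_type must be H or L")


def position_aa_distribution(
    dataset: PairedDataset, chain_type: str, position: str
) -> AADistribution:
    """Amino-acid distribution at one IMGT position across a dataset.

    Records lacking the position (shorter loops / gaps) are excluded from n.
    """
    position = str(position)
    counts: dict[str, int] = {}
    for rec in dataset:
        aa = _chain(rec, chain_type).imgt_positions.get(position)
        if aa is None:
            continue
        counts[aa] = counts.get(aa, 0) + 1
    if not counts:
        raise EmptyResultError(f"position {position} observed in zero records")
    return AADistribution(
        position=position, chain_type=chain_type, counts=counts, n=sum(counts.values())
    )


def total_variation_distance(d1: AADistribution, d2: AADistribution) -> float:
    """Total Variation Distance between two per-position distributions."""
    return tvd(d1.proportions, d2.proportions)


def tvd(p1: Mapping, p2: Mapping) -> float:
    """1/2 * L1 distance between two discrete distributions (union of supports).

    Clamped to [0, 1]: inputs normalized in floating point can overshoot the
    bound by a few ulp.
    """
    support = set(p1) | set(p2)
    d = 0.5 * sum(abs(p1.get(s, 0.0) - p2.get(s, 0.0)) for s in support)
    return min(1.0, max(0.0, float(d)))


def position_gof_test(
    reference: AADistribution, compared: AADistribution, min_bin: int = 5
) -> tuple[float, int, float]:
    """Chi-square goodness of fit of ``compared`` counts against ``reference``.

    Expected counts are reference proportions scaled to ``compared.n``.
    Symbols observed fewer than ``min_bin`` times in the compared dataset are
    pooled into "other", with the corresponding expected mass (including any
    reference-only symbols) pooled in parallel — totals are conserved.
    Returns (statistic, df = bins - 1, p). Bonferroni across positions is the
    caller's responsibility.
    """
    ref_p = reference.proportions
    uncovered = [aa for aa, c in compared.counts.items() if c >= min_bin and aa not in ref_p]
    if uncovered:
        raise DataError(
            f"reference does not cover compared symbols {sorted(uncovered)} after binning"
        )
    keep = sorted(aa for aa, c in compared.counts.items() if c >= min_bin)
    observed = [compared.counts[aa] for aa in keep]
    expected = [ref_p[aa] * compared.n for aa in keep]
    pooled_obs = compared.n - sum(observed)
    pooled_exp = compared.n - sum(expected)
    if pooled_obs > 0 or pooled_exp > 1e-12:
        observed.append(pooled_obs)
        expected.append(pooled_exp)
    if len(observed) < 2:
        raise TestNotApplicableError("fewer than 2 bins after pooling")
    stat, p = chisquare(f_obs=observed, f_exp=expected)
    return float(stat), len(observed) - 1, float(p)


# ---------------------------------------------------------------------------
# joint H/L pair distributions
# ---------------------------------------------------------------------------

def _paired_symbols(dataset: PairedDataset, h_position: str, l_position: str):
    """(aa_H, aa_L) observations over records where both positions are present."""
    h_position, l_position = str(h_position), str(l_position)
    pairs = []
    for rec in dataset:
        h = rec.heavy.imgt_positions.get(h_position)
        l = rec.light.imgt_positions.get(l_position)
        if h is None or l is None:
            continue
        pairs.append((h, l))
    return pairs


def joint_pair_distribution(
    dataset: PairedDataset, h_position: str, l_position: str
) -> PairAADistribution:
    """Joint amino-acid-pair proportions at an (H, L) position pair."""
    pairs = _paired_symbols(dataset, h_position, l_position)
    if not pairs:
        raise EmptyResultError(
            f"no records carry both H:{h_position} and L:{l_position}"
        )
    counts: dict[tuple[str, str], int] = {}
    for hl in pairs:
        counts[hl] = counts.get(hl, 0) + 1
    n = len(pairs)
    return PairAADistribution(
        h_position=str(h_position),
        l_position=str(l_position),
        joint={hl: c / n for hl, c in counts.items()},
        n=n,
    )


def random_pairing_reference(
    dataset: PairedDataset,
    h_position: str,
    l_position: str,
    mode: str = "analytic",
    seed: int | None = None,
) -> PairAADistribution:
    """Joint distribution expected if heavy and light chains paired at random.

    ``analytic`` mode returns the exact outer product of the two marginal
    distributions (no Monte-Carlo noise); ``permutation`` mode shuffles the
    light-chain symbols across records once with a seeded RNG and tabulates
    the resulting joint.
    """
    pairs = _paired_symbols(dataset, h_position, l_position)
    if not pairs:
        raise EmptyResultError(
            f"no records carry both H:{h_position} and L:{l_position}"
        )
    n = len(pairs)
    if mode == "analytic":
        h_marg: dict[str, float] = {}
        l_marg: dict[str, float] = {}
        for h, l in pairs:
            h_marg[h] = h_marg.get(h, 0.0) + 1.0 / n
            l_marg[l] = l_marg.get(l, 0.0) + 1.0 / n
        joint = {(h, l): ph * pl for h, ph in h_marg.items() for l, pl in l_marg.items()}
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        h_syms = [h for h, _ in pairs]
        l_syms = [l for _, l in pairs]
        perm = rng.permutation(n)
        counts: dict[tuple[str, str], int] = {}
        for i, h in enumerate(h_syms):
            hl = (h, l_syms[perm[i]])
            counts[hl] = counts.get(hl, 0) + 1
        joint = {hl: c / n for hl, c in counts.items()}
    else:
        raise DataError("mode must be 'analytic' or 'permutation'")
    return PairAADistribution(
        h_position=str(h_position), l_position=str(l_position), joint=joint, n=n
    )


def pair_tvd(observed: PairAADistribution, reference: PairAADistribution) -> float:
    """Total Variation Distance between two joint pair distributions."""
    return tvd(observed.joint, reference.joint)
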