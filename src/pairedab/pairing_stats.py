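"""Germline pairing-preference statistics for paired heavy/light repertoires.

The central question: do heavy and light germline genes pair at the rates
their individual usage frequencies predict, or are certain combinations
enriched beyond chance (e.g. through receptor editing selecting against
autoreactive pairings)?

Machinery:

* a contingency table of heavy-chain feature x light-chain feature counts
  (V subgroup by default; the inter-chain V-J analysis is the same code with
  a J-gene selector), with the rare-pair mask (observed co-occurrence < 5
  excluded from testing);
* a global chi-square test of independence on the whole table;
* per-pair 2x2 enrichment tests (each pair against the aggregate of all
  other subgroups), Yates-corrected, Bonferroni-adjusted over the tests
  actually performed;
* a G x 2 usage-comparison chi-square between two datasets' germline counts;
* descriptive repertoire summaries (kappa:lambda ratios, c_call usage).

All chi-square computations delegate to scipy.stats.chi2_contingency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .errors import DataError, EmptyResultError, TestNotApplicableError
from .io_formats import ChainAnnotation, PairedDataset

FeatureSelector = Callable[[ChainAnnotation], str]

#: named feature selectors for pairing_counts
FEATURE_SELECTORS: dict[str, FeatureSelector] = {
    "v_subgroup": lambda c: _require_call(c.v_call, "v_call").subgroup,
    "j_subgroup": lambda c: _require_call(c.j_call, "j_call").subgroup,
    "v_gene": lambda c: _require_call(c.v_call, "v_call").gene
    or _require_call(c.v_call, "v_call").subgroup,
    "j_gene": lambda c: _require_call(c.j_call, "j_call").gene
    or _require_call(c.j_call, "j_call").subgroup,
}


def _require_call(call, name: str):
    if call is None:
        raise DataError(f"record lacks a {name} annotation")
    return call


def _resolve(selector: str | FeatureSelector) -> FeatureSelector:
    if callable(selector):
        return selector
    try:
        return FEATURE_SELECTORS[selector]
    except KeyError:
        raise DataError(
            f"unknown feature selector {selector!r}; known: {sorted(FEATURE_SELECTORS)}"
        ) from None


@dataclass
class PairingTable:
    """Cross-tabulated heavy x light feature counts with a rare-pair mask.

    ``masked`` cells (count below the configured minimum) are excluded from
    statistical testing, but their counts still contribute to the marginals
    and ``n_total`` used for per-pair expectations.
    """

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # integer matrix, rows = heavy feature
    masked: set[tuple[str, str]] = field(default_factory=set)
    n_total: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise DataError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise DataError("negative counts")
        if not self.n_total:
            self.n_total = int(self.counts.sum())

    def count(self, row: str, col: str) -> int:
        return int(self.counts[self.row_labels.index(row), self.col_labels.index(col)])

    def unmasked_cells(self) -> list[tuple[int, int]]:
        return [
            (i, j)
            for i in range(len(self.row_labels))
            for j in range(len(self.col_labels))
            if (self.row_labels[i], self.col_labels[j]) not in self.masked
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass(frozen=True)
class PairTestResult:
    """Outcome of one per-pair 2x2 enrichment test."""

    pair: tuple[str, str]
    observed: int
    expected: float
    statistic: float
    p_raw: float
    p_adjusted: float
    direction: str  # "enriched" | "depleted"
    rejected: bool


def pairing_counts(
    dataset: PairedDataset,
    heavy_feature: str | FeatureSelector = "v_subgroup",
    light_feature: str | FeatureSelector = "v_subgroup",
    min_pair_count: int = 5,
    light_locus: str = "both",
) -> PairingTable:
    """Cross-tabulate a heavy-chain feature against a light-chain feature.

    ``light_locus`` restricts the light chains to kappa (IGK), lambda (IGL)
    or keeps both, mirroring the separate kappa/lambda analyses. Cells with
    fewer than ``min_pair_count`` co-occurrences are masked.
    """
    if light_locus not in ("IGK", "IGL", "both"):
        raise DataError("light_locus must be IGK, IGL or 'both'")
    h_sel = _resolve(heavy_feature)
    l_sel = _resolve(light_feature)
    pairs: dict[tuple[str, str], int] = {}
    for rec in dataset:
        if light_locus != "both" and rec.light.locus != light_locus:
            continue
        key = (h_sel(rec.heavy), l_sel(rec.light))
        pairs[key] = pairs.get(key, 0) + 1
    if not pairs:
        raise EmptyResultError("no records matched the requested light locus")
    row_labels = sorted({h for h, _ in pairs})
    col_labels = sorted({l for _, l in pairs})
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
    for (h, l), n in pairs.items():
        counts[row_labels.index(h), col_labels.index(l)] = n
    masked = {
        (h, l)
        for i, h in enumerate(row_labels)
        for j, l in enumerate(col_labels)
        if counts[i, j] < min_pair_count
    }
    if len(masked) == len(row_labels) * len(col_labels):
        raise EmptyResultError("all cells fall below min_pair_count")
    return PairingTable(row_labels=row_labels, col_labels=col_labels, counts=counts, masked=masked)


def global_independence_test(table: PairingTable) -> tuple[float, int, float]:
    """Global chi-square test of heavy/light feature independence.

    Masked (rare) cells are excluded entirely — their counts are zeroed
    before the test, matching the source analysis where pairs observed fewer
    than five times were filtered out. All-zero rows/columns are dropped;
    Yates continuity correction applies only to the 2x2 case.
    Returns (statistic, degrees of freedom, p-value).
    """
    counts = table.counts.copy()
    for (h, l) in table.masked:
        counts[table.row_labels.index(h), table.col_labels.index(l)] = 0
    keep_rows = counts.sum(axis=1) > 0
    keep_cols = counts.sum(axis=0) > 0
    counts = counts[keep_rows][:, keep_cols]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise TestNotApplicableError(
            "independence test needs >=2 rows and >=2 columns after dropping empty ones"
        )
    res = chi2_contingency(counts, correction=(counts.shape == (2, 2)))
    return float(res.statistic), int(res.dof), float(res.pvalue)


def per_pair_enrichment(table: PairingTable, alpha: float = 0.05) -> list[PairTestResult]:
    """Per-pair 2x2 enrichment tests against the aggregated complement.

    For each unmasked cell (h, l) the 2x2 table is
    [[n_hl, n_hl'], [n_h'l, n_h'l']] where h'/l' aggregate all other
    subgroups. Yates-corrected chi-square per cell; Bonferroni over the
    number of tests actually performed. ``direction`` is "enriched" when the
    observed count exceeds the marginal-product expectation.
    """
    if len(table.row_labels) < 2 or len(table.col_labels) < 2:
        raise TestNotApplicableError("per-pair tests need >=2 rows and >=2 columns")
    n = table.n_total
    row_tot = table.counts.sum(axis=1)
    col_tot = table.counts.sum(axis=0)
    raw: list[tuple[tuple[str, str], int, float, float, float]] = []
    for i, j in table.unmasked_cells():
        a = int(table.counts[i, j])
        b = int(row_tot[i] - a)
        c = int(col_tot[j] - a)
        d = int(n - a - b - c)
        expected = row_tot[i] * col_tot[j] / n
        contingency = np.array([[a, b], [c, d]], dtype=np.int64)
        if contingency.sum(axis=0).min() == 0 or contingency.sum(axis=1).min() == 0:
            continue  # degenerate margin: the cell IS a full row/column
        res = chi2_contingency(contingency, correction=True)
        raw.append(
            ((table.row_labels[i], table.col_labels[j]), a, float(expected),
             float(res.statistic), float(res.pvalue))
        )
    n_tests = len(raw)
    results = []
    for pair, observed, expected, stat, p in raw:
        p_adj = min(1.0, p * n_tests)
        results.append(
            PairTestResult(
                pair=pair,
                observed=observed,
                expected=expected,
                statistic=stat,
                p_raw=p,
                p_adjusted=p_adj,
                direction="enriched" if observed > expected else "depleted",
                rejected=p_adj < alpha,
            )
        )
    return results


def preferential_pairs(results: list[PairTestResult]) -> list[tuple[str, str]]:
    """Pairs that are rejected AND enriched (the 'preferential pairing' display)."""
    return [r.pair for r in results if r.rejected and r.direction == "enriched"]


def results_to_frame(results: list[PairTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "heavy": [r.pair[0] for r in results],
            "light": [r.pair[1] for r in results],
            "observed": [r.observed for r in results],
            "expected": [r.expected for r in results],
            "statistic": [r.statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "direction": [r.direction for r in results],
            "rejected": [r.rejected for r in results],
        }
    )


def usage_comparison_test(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int]
) -> tuple[float, int, float]:
    """Chi-square test that two datasets share germline usage proportions.

    Builds the G x 2 table over the union of features (a feature absent from
    one dataset counts 0 there). Returns (statistic, df = G - 1, p-value).
    """
    features = sorted(set(counts_a) | set(counts_b))
    if len(features) < 2:
        raise TestNotApplicableError("usage comparison needs >=2 features")
    tbl = np.array(
        [[int(counts_a.get(f, 0)), int(counts_b.get(f, 0))] for f in features], dtype=np.int64
    )
    keep = tbl.sum(axis=1) > 0
    tbl = tbl[keep]
    if tbl.shape[0] < 2 or (tbl.sum(axis=0) == 0).any():
        raise TestNotApplicableError("usage comparison table is degenerate")
    res = chi2_contingency(tbl, correction=(tbl.shape == (2, 2)))
    return float(res.statistic), int(res.dof), float(res.pvalue)


def summarize_repertoire(dataset: PairedDataset) -> dict[str, pd.DataFrame]:
    """Descriptive summary tables: light-locus, c_call and per-study breakdowns.

    Returns a dict of DataFrames:

    * ``light_locus`` — counts and proportions of kappa vs lambda, pooled;
    * ``kappa_lambda`` — per-study rows plus a pooled row with the
      kappa:lambda split;
    * ``c_call`` — constant-gene usage for heavy and light chains;
    * ``study`` — record counts per study.
    """
    if not len(dataset):
        raise EmptyResultError("empty dataset")
    rows = [
        {
            "study_id": r.study_id,
            "light_locus": r.light.locus,
            "heavy_c": r.heavy.c_call.subgroup if r.heavy.c_call else "unassigned",
            "light_c": r.light.c_call.subgroup if r.light.c_call else "unassigned",
        }
        for r in dataset
    ]
    df = pd.DataFrame(rows)

    locus = df["light_locus"].value_counts().rename_axis("light_locus").to_frame("count")
    locus["proportion"] = locus["count"] / locus["count"].sum()

    def _kl(group: pd.DataFrame) -> pd.Series:
        n_k = int((group["light_locus"] == "IGK").sum())
        n_l = int((group["light_locus"] == "IGL").sum())
        total = n_k + n_l
        return pd.Series(
            {
                "n_kappa": n_k,
                "n_lambda": n_l,
                "frac_kappa": n_k / total if total else float("nan"),
                "frac_lambda": n_l / total if total else float("nan"),
            }
        )

    per_study = df.groupby("study_id", sort=True).apply(_kl, include_groups=False)
    pooled = _kl(df).to_frame().T
    pooled.index = ["pooled"]
    kappa_lambda = pd.concat([per_study, pooled])

    c_call = pd.concat(
        [
            df["heavy_c"].value_counts().rename_axis("c_call").to_frame("count").assign(chain="heavy"),
            df["light_c"].value_counts().rename_axis("c_call").to_frame("count").assign(chain="light"),
        ]
    )
    study = df["study_id"].value_counts().rename_axis("study_id").to_frame("n_records")
    return {"light_locus": locus, "kappa_lambda": kappa_lambda, "c_call": c_call, "study": study}
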