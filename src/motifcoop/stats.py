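"""Pair-level significance testing.

For each motif pair the per-sequence attention attributes in positive
sequences are compared with those in negative sequences by a one-sided
Mann-Whitney U test (positive > negative); sequences in which the pair never
co-occurs contribute no record.  Low-confidence predictions are removed
first: positive sequences with sigmoid score < 0.7 and negative sequences
with score > 0.3.  Raw p-values are Bonferroni-corrected over the number of
pairs actually tested, and pairs with adjusted p below 1e-4 are reported,
sorted ascending by adjusted p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .pairs import spacing_summary

POS_SCORE_MIN = 0.7
NEG_SCORE_MAX = 0.3
SIGNIFICANCE_ALPHA = 1e-4

#: pairs with fewer contributing sequences than this are listed as untested
MIN_POS_RECORDS = 10
MIN_NEG_RECORDS = 5


@dataclass(frozen=True)
class PairTestResult:
    pair: str
    motif_a: str
    motif_b: str
    n_pos: int
    n_neg: int
    mean_attr_pos: float
    mean_attr_neg: float
    u_statistic: float
    p_raw: float
    p_adj: float
    significant: bool
    spacing_mean: float
    spacing_sd: float
    gap_mean: float
    gap_sd: float


def filter_by_prediction(records: pd.DataFrame, scores: dict[str, float]
                         ) -> pd.DataFrame:
    """Drop records from low-confidence sequences.

    Positive-sequence records are kept iff the prediction score is >= 0.7;
    negative-sequence records iff it is <= 0.3.
    """
    if records.empty:
        return records
    s = records["seq_id"].map(scores)
    if s.isna().any():
        missing = records.loc[s.isna(), "seq_id"].unique()[:5]
        raise KeyError(f"no prediction score for sequence(s) {list(missing)}")
    keep = np.where(records["label"] == "positive",
                    s >= POS_SCORE_MIN, s <= NEG_SCORE_MAX)
    return records.loc[keep].reset_index(drop=True)


def mann_whitney_pair(pos_attrs, neg_attrs) -> tuple[float, float]:
    """One-sided Mann-Whitney U test of positive > negative.

    U counts pairs with x > y plus half the ties.  The exact null
    distribution is used when the smaller sample has <= 20 values and there
    are no ties; otherwise the normal approximation with tie correction.
    All-identical inputs are degenerate and return p = 1.
    """
    pos = np.asarray(list(pos_attrs), dtype=float)
    neg = np.asarray(list(neg_attrs), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([pos, neg])
    if np.all(combined == combined[0]):
        return float(pos.size * neg.size / 2.0), 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (min(pos.size, neg.size) <= 20 and not has_ties) \
        else "asymptotic"
    res = mannwhitneyu(pos, neg, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_raw, n_tests: int | None = None) -> np.ndarray:
    """Family-wise correction: ``p_adj = min(1, p * n_tests)``."""
    p = np.asarray(list(p_raw), dtype=float)
    n = p.size if n_tests is None else n_tests
    return np.minimum(1.0, p * n)


def test_pairs(records: pd.DataFrame, scores: dict[str, float],
               min_pos: int = MIN_POS_RECORDS, min_neg: int = MIN_NEG_RECORDS,
               alpha: float = SIGNIFICANCE_ALPHA,
               include_self: bool = False, prefiltered: bool = False,
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every motif pair's attributes, positives vs negatives.

    Returns ``(results, untested)``.  ``results`` has one row per tested
    pair, sorted ascending by adjusted p (ties broken by descending mean
    positive attribute); ``untested`` lists pairs failing the minimum-count
    rule with their counts.  Spacing statistics are computed over
    positive-sequence records only.  ``prefiltered`` skips the prediction
    filter when the caller already applied it.
    """
    recs = records if prefiltered else filter_by_prediction(records, scores)
    if not include_self:
        recs = recs.loc[~recs["is_self"]]
    tested_rows: list[PairTestResult] = []
    untested_rows = []
    for (ma, mb), grp in recs.groupby(["motif_a", "motif_b"], sort=True):
        pos = grp.loc[grp["label"] == "positive"]
        neg = grp.loc[grp["label"] == "negative"]
        if len(pos) < min_pos or len(neg) < min_neg:
            untested_rows.append({"pair": f"{ma}::{mb}", "motif_a": ma,
                                  "motif_b": mb, "n_pos": len(pos),
                                  "n_neg": len(neg)})
            continue
        u, p = mann_whitney_pair(pos["attribute"], neg["attribute"])
        sp_mean, sp_sd = spacing_summary(pos["spacing_bp"])
        gap_mean, gap_sd = spacing_summary(pos["gap_bp"])
        tested_rows.append(PairTestResult(
            pair=f"{ma}::{mb}", motif_a=ma, motif_b=mb,
            n_pos=len(pos), n_neg=len(neg),
            mean_attr_pos=float(pos["attribute"].mean()),
            mean_attr_neg=float(neg["attribute"].mean()),
            u_statistic=u, p_raw=p, p_adj=np.nan, significant=False,
            spacing_mean=sp_mean, spacing_sd=sp_sd,
            gap_mean=gap_mean, gap_sd=gap_sd))
    columns = list(PairTestResult.__dataclass_fields__)
    results = pd.DataFrame([vars(r) for r in tested_rows], columns=columns)
    if not results.empty:
        results["p_adj"] = bonferroni(results["p_raw"], len(results))
        results["significant"] = results["p_adj"] < alpha
        results = results.sort_values(
            ["p_adj", "mean_attr_pos", "pair"],
            ascending=[True, False, True]).reset_index(drop=True)
    untested = pd.DataFrame(untested_rows,
                            columns=["pair", "motif_a", "motif_b",
                                     "n_pos", "n_neg"])
    return results, untested


def rank_significant(results: pd.DataFrame,
                     alpha: float = SIGNIFICANCE_ALPHA) -> pd.DataFrame:
    """Pairs with adjusted p below ``alpha``, best first."""
    if results.empty:
        return results
    sig = results.loc[results["p_adj"] < alpha]
    return sig.sort_values(["p_adj", "mean_attr_pos", "pair"],
                           ascending=[True, False, True]).reset_index(drop=True)
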