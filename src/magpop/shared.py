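"""Downcore genetic-variability statistics: shared SNVs, consensus agreement,
inter- vs intra-core comparisons and the F_ST regressions.

An *inter-core* comparison pairs samples of the same sediment horizon taken
from replicate cores at one site; an *intra-core* comparison pairs different
horizons of the same core. The fraction of SNV positions shared by a pair,
and the fraction of those with the same consensus base, move opposite to
F_ST when convergent selection homogenizes replicate populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateFitError, ValidationError
from .fst import FstMatrix
from .io import SampleRecord, logger

SHARED_DENOMINATORS = ("union", "min", "mean")

PAIR_COLUMNS = [
    "mag_id",
    "sample_x",
    "sample_y",
    "kind",
    "fst",
    "pct_shared",
    "pct_same_consensus",
    "n_x",
    "n_y",
    "n_shared",
    "horizon",
]


def shared_snv_stats(
    snvs_x: pd.DataFrame,
    snvs_y: pd.DataFrame,
    denominator: str = "union",
) -> tuple[float, float, int]:
    """Shared-SNV fraction and same-consensus fraction for one sample pair.

    Both inputs are SNV records (with consensus) already restricted to
    positions covered above threshold in *both* samples. The shared fraction
    is |X & Y| over the chosen denominator (default the union, a symmetric
    Jaccard index); the same-consensus fraction is computed over shared
    positions only. Returns (0.0, 0.0, 0) when the union is empty; an empty
    intersection yields same-consensus 0 by convention.
    """
    if denominator not in SHARED_DENOMINATORS:
        raise ValidationError(f"unknown shared denominator {denominator!r}")
    key = ["contig_id", "position"]
    cons_x = {tuple(k): c for *k, c in snvs_x[key + ["consensus"]].itertuples(index=False)}
    cons_y = {tuple(k): c for *k, c in snvs_y[key + ["consensus"]].itertuples(index=False)}
    x_set, y_set = set(cons_x), set(cons_y)
    inter = x_set & y_set
    union = x_set | y_set
    if not union:
        return 0.0, 0.0, 0
    if denominator == "union":
        denom = len(union)
    elif denominator == "min":
        denom = min(len(x_set), len(y_set)) or len(union)
    else:
        denom = (len(x_set) + len(y_set)) / 2.0 or len(union)
    pct_shared = len(inter) / denom
    if not inter:
        logger.info("shared_snv_stats: empty intersection; same-consensus set to 0")
        return pct_shared, 0.0, 0
    same = sum(1 for p in inter if cons_x[p] == cons_y[p])
    return pct_shared, same / len(inter), len(inter)


def classify_pair(rec_x: SampleRecord, rec_y: SampleRecord) -> str:
    """inter_core / intra_core / other for one unordered sample pair."""
    if (
        rec_x.site_id == rec_y.site_id
        and rec_x.horizon == rec_y.horizon
        and rec_x.core_id != rec_y.core_id
    ):
        return "inter_core"
    if (
        rec_x.site_id == rec_y.site_id
        and rec_x.core_id == rec_y.core_id
        and rec_x.horizon != rec_y.horizon
    ):
        return "intra_core"
    return "other"


def classify_pairs(matrix: FstMatrix, metadata: list[SampleRecord]) -> pd.DataFrame:
    """Label every unordered pair of the matrix as inter/intra-core or other."""
    by_id = {rec.sample_id: rec for rec in metadata}
    missing = [s for s in matrix.sample_ids if s not in by_id]
    if missing:
        raise ValidationError(f"sample(s) missing metadata: {missing}")
    rows = []
    ids = matrix.sample_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rec_x, rec_y = by_id[ids[i]], by_id[ids[j]]
            kind = classify_pair(rec_x, rec_y)
            rows.append(
                {
                    "mag_id": matrix.mag_id,
                    "sample_x": ids[i],
                    "sample_y": ids[j],
                    "kind": kind,
                    "fst": float(matrix.values[i, j]),
                    "horizon": rec_x.horizon if kind == "inter_core" else "",
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        counts = df["kind"].value_counts().to_dict()
        logger.info("classify_pairs: %s", counts)
    return df


def build_pair_comparisons(
    counts: pd.DataFrame,
    snvs: pd.DataFrame,
    matrix: FstMatrix,
    metadata: list[SampleRecord],
    min_coverage: int = 10,
    shared_denominator: str = "union",
) -> pd.DataFrame:
    """Full PairComparison table: kind, F_ST, shared-SNV statistics per pair.

    For each pair, SNV sets are first restricted to positions covered >=
    min_coverage in both samples (the pairwise core positions), so coverage
    differences cannot masquerade as variability differences.
    """
    from .io import BASES

    pairs = classify_pairs(matrix, metadata)
    cov = counts.copy()
    cov["coverage"] = cov[list(BASES)].sum(axis=1)
    cov_by_sample = {
        s: dict(zip(zip(g["contig_id"], g["position"]), g["coverage"]))
        for s, g in cov.groupby("sample_id")
    }
    snv_by_sample = {s: g for s, g in snvs.groupby("sample_id")}
    empty = snvs.iloc[0:0]
    records = []
    for row in pairs.itertuples(index=False):
        sx, sy = row.sample_x, row.sample_y
        cov_x = cov_by_sample.get(sx, {})
        cov_y = cov_by_sample.get(sy, {})
        core = {
            p for p, c in cov_x.items() if c >= min_coverage and cov_y.get(p, 0) >= min_coverage
        }

        def restrict(sample_snvs):
            if not len(sample_snvs):
                return sample_snvs
            keys = list(zip(sample_snvs["contig_id"], sample_snvs["position"]))
            mask = [k in core for k in keys]
            return sample_snvs[mask]

        snv_x = restrict(snv_by_sample.get(sx, empty))
        snv_y = restrict(snv_by_sample.get(sy, empty))
        pct_shared, pct_same, n_shared = shared_snv_stats(
            snv_x, snv_y, denominator=shared_denominator
        )
        records.append(
            {
                **row._asdict(),
                "pct_shared": pct_shared,
                "pct_same_consensus": pct_same,
                "n_x": len(snv_x),
                "n_y": len(snv_y),
                "n_shared": n_shared,
            }
        )
    return pd.DataFrame(records, columns=PAIR_COLUMNS)


def intercore_vs_intracore_test(pairs: pd.DataFrame) -> tuple[float, float, dict]:
    """Kruskal-Wallis rank-sum test of inter-core vs intra-core F_ST.

    Returns (H, p_value, group medians). Two groups, so H follows a
    chi-square with 1 df under the null; scipy applies the tie correction.
    """
    inter = pairs.loc[pairs["kind"] == "inter_core", "fst"].to_numpy(dtype=float)
    intra = pairs.loc[pairs["kind"] == "intra_core", "fst"].to_numpy(dtype=float)
    if inter.size == 0 or intra.size == 0:
        raise ValidationError("both inter-core and intra-core groups must be non-empty")
    medians = {"inter_core": float(np.median(inter)), "intra_core": float(np.median(intra))}
    if np.unique(np.concatenate([inter, intra])).size == 1:
        # every observation tied: no evidence of a difference (scipy raises here)
        return 0.0, 1.0, medians
    h_stat, p_value = stats.kruskal(inter, intra)
    return float(h_stat), float(p_value), medians


@dataclass
class RegressionFit:
    """Ordinary least-squares fit summary."""

    predictor: str
    slope: float
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    p_value: float
    n: int


def ols_fit(x, y, predictor: str = "x") -> RegressionFit:
    """Closed-form OLS of y on x with adjusted R^2 and two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise DegenerateFitError(f"OLS needs n >= 3, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero predictor variance")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionFit(
        predictor=predictor,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        adjusted_r_squared=adj,
        p_value=float(res.pvalue),
        n=int(n),
    )


def fit_fst_regressions(
    pairs: pd.DataFrame,
    predictors: tuple[str, ...] = ("pct_shared", "pct_same_consensus"),
    response: str = "fst",
    kind: str = "inter_core",
) -> dict[str, RegressionFit]:
    """OLS of F_ST on each shared-variant predictor over inter-core pairs.

    One point per inter-core pair per horizon (pooled across horizons), the
    pairing structure of the downcore comparison.
    """
    sub = pairs[pairs["kind"] == kind] if kind else pairs
    fits = {}
    for predictor in predictors:
        fits[predictor] = ols_fit(
            sub[predictor].to_numpy(dtype=float),
            sub[response].to_numpy(dtype=float),
            predictor=predictor,
        )
    return fits


def horizon_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-horizon means of inter-core F_ST and shared-variant fractions."""
    inter = pairs[pairs["kind"] == "inter_core"]
    if inter.empty:
        raise ValidationError("no inter-core pairs to summarize")
    return (
        inter.groupby("horizon")[["fst", "pct_shared", "pct_same_consensus"]]
        .mean()
        .reset_index()
    )
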