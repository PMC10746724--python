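"""SNV calling, coverage/detection summaries and density statistics.

A single nucleotide variant (SNV) is a genome position where, in one sample,
the fraction of mapped reads not matching the consensus base (the "departure
from consensus") reaches a threshold, subject to a minimum coverage. All
coverage thresholds in this package are inclusive (>=): one auditable
convention for position filters and MAG selection alike. The departure
threshold is likewise inclusive, and detection uses a strict ">" because the
abundance-proxy rule zeroes coverage unless breadth of coverage is *over*
the cutoff.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import BASES, log_filter, logger


def consensus_and_departure(count_A: int, count_C: int, count_G: int, count_T: int):
    """Consensus base and departure from consensus for one position.

    Departure is the number of reads not matching the consensus divided by
    the total number of mapped reads. Ties in the maximal count resolve to
    the earliest base in A < C < G < T order.

    Raises ValidationError on zero coverage (the position is undefined).
    """
    counts = (count_A, count_C, count_G, count_T)
    coverage = sum(counts)
    if coverage <= 0:
        raise ValidationError("consensus undefined at zero coverage")
    idx = max(range(4), key=lambda i: (counts[i], -i))  # -i: earliest base wins ties
    return BASES[idx], (coverage - counts[idx]) / coverage


def _annotate(counts: pd.DataFrame) -> pd.DataFrame:
    """Add coverage, consensus and departure columns to a count table."""
    arr = counts[list(BASES)].to_numpy(dtype=np.int64)
    coverage = arr.sum(axis=1)
    if (coverage <= 0).any():
        raise ValidationError("zero-coverage row in count table")
    cons_idx = arr.argmax(axis=1)  # argmax returns the first maximum: A < C < G < T
    out = counts.copy()
    out["coverage"] = coverage
    out["consensus"] = np.array(BASES, dtype=object)[cons_idx]
    out["departure"] = (coverage - arr[np.arange(len(arr)), cons_idx]) / coverage
    return out


def call_snvs(counts: pd.DataFrame, min_coverage: int = 10, min_departure: float = 0.1) -> pd.DataFrame:
    """Filter a BaseCountTable down to SNV records.

    A record is kept iff coverage >= min_coverage and departure >=
    min_departure (both inclusive). Returns the table with added coverage,
    consensus and departure columns. Per-sample retained counts are logged.
    """
    if min_coverage <= 0 or min_departure <= 0:
        raise ValidationError("thresholds must be positive")
    if counts.empty:
        out = counts.copy()
        for col, dtype in (("coverage", np.int64), ("consensus", object), ("departure", float)):
            out[col] = pd.Series(dtype=dtype)
        return out
    annotated = _annotate(counts)
    mask = (annotated["coverage"] >= min_coverage) & (annotated["departure"] >= min_departure)
    out = annotated[mask].reset_index(drop=True)
    log_filter("call_snvs", len(annotated), len(out))
    for sample, n in out.groupby("sample_id", sort=True).size().items():
        logger.info("call_snvs: sample %s: %d SNVs", sample, n)
    return out


def core_positions(counts: pd.DataFrame, sample_ids, min_coverage: int = 10) -> pd.DataFrame:
    """Positions covered >= min_coverage in *every* listed sample.

    Positions absent from the table for a sample count as coverage 0 there.
    Returns a DataFrame with columns (mag_id, contig_id, position). Adding a
    sample to ``sample_ids`` can only shrink the result.
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValidationError("sample_ids must be non-empty")
    present = set(counts["sample_id"].unique())
    missing = [s for s in sample_ids if s not in present]
    if missing:
        raise ValidationError(f"sample(s) absent from count table: {missing}")
    sub = counts[counts["sample_id"].isin(sample_ids)]
    cov = sub[list(BASES)].sum(axis=1)
    key = sub[["mag_id", "contig_id", "position"]].copy()
    key["ok"] = (cov >= min_coverage).to_numpy()
    grouped = key.groupby(["mag_id", "contig_id", "position"], sort=True)["ok"].agg(["sum", "size"])
    # a position qualifies when all listed samples have a row passing the filter
    good = grouped[(grouped["size"] == len(sample_ids)) & (grouped["sum"] == len(sample_ids))]
    return good.reset_index()[["mag_id", "contig_id", "position"]]


def coverage_summary(counts: pd.DataFrame, mag_lengths: dict, min_detection: float = 0.7) -> pd.DataFrame:
    """Per (MAG, sample) mean coverage, detection and the reported proxy.

    detection = fraction of MAG positions covered by at least one read;
    mean_coverage averages over all MAG positions (absent positions count 0);
    reported_coverage = mean_coverage when detection > min_detection
    (strictly), else 0.
    """
    rows = []
    for (mag, sample), grp in counts.groupby(["mag_id", "sample_id"], sort=True):
        if mag not in mag_lengths:
            raise ValidationError(f"no length given for MAG {mag!r}")
        length = int(mag_lengths[mag])
        if length <= 0:
            raise ValidationError(f"MAG {mag!r}: length must be positive")
        if (grp["position"] >= length).any():
            raise ValidationError(f"MAG {mag!r}: position beyond MAG length {length}")
        cov = grp[list(BASES)].sum(axis=1)
        detection = float((cov > 0).sum()) / length
        mean_cov = float(cov.sum()) / length
        rows.append(
            {
                "mag_id": mag,
                "sample_id": sample,
                "mean_coverage": mean_cov,
                "detection": detection,
                "reported_coverage": mean_cov if detection > min_detection else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["mag_id", "sample_id", "mean_coverage", "detection", "reported_coverage"])


def apply_detection_rule(summary: pd.DataFrame, min_detection: float = 0.7) -> pd.DataFrame:
    """(Re-)apply the abundance-proxy rule to an existing coverage summary."""
    out = summary.copy()
    out["reported_coverage"] = np.where(
        out["detection"] > min_detection, out["mean_coverage"], 0.0
    )
    return out


def snv_density(snvs, covered_length_bp: int) -> float:
    """SNV density in SNVs per kilobase of the covered comparison support.

    ``snvs`` is a DataFrame of SNV records (or an integer count). The
    denominator is chosen by the caller: by default the pipeline uses the
    core-position support (positions >= 10x in every sample of the
    comparison group) so that coverage differences cannot influence the
    detection rate.
    """
    n = int(snvs) if np.isscalar(snvs) else len(snvs)
    if covered_length_bp <= 0:
        raise ValidationError("snv_density: covered length must be positive")
    return 1000.0 * n / covered_length_bp


def select_mags(coverage: pd.DataFrame, min_cov: float = 10, min_samples: int = 40) -> list[str]:
    """MAGs whose per-sample mean coverage is >= min_cov in >= min_samples samples."""
    if coverage.empty:
        return []
    ok = coverage[coverage["mean_coverage"] >= min_cov]
    counts = ok.groupby("mag_id")["sample_id"].nunique()
    return sorted(counts[counts >= min_samples].index)


def samples_covering(coverage: pd.DataFrame, mag_id: str, min_cov: float = 10) -> list[str]:
    """Samples in which a MAG has mean coverage >= min_cov (sorted)."""
    sub = coverage[(coverage["mag_id"] == mag_id) & (coverage["mean_coverage"] >= min_cov)]
    return sorted(sub["sample_id"].unique())
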