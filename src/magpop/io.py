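"""Readers and writers for the tables the pipeline touches.

All tabular formats are tab-separated UTF-8 with a header row. Positions are
0-based internally and on disk; the ``anvio`` dialect of the variability
table is also interpreted as 0-based, so no conversion happens at the
boundary. Dendrograms are exported as Newick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError

logger = logging.getLogger("magpop")

TRENCH_SYSTEMS = frozenset({"Atacama", "Kermadec"})
REALMS = frozenset({"abyssal", "hadal"})
GEOCHEM_ZONES = frozenset({"oxic", "nitrogenous", "ferruginous"})

#: canonical base order; ties in consensus calls resolve to the earliest base
BASES = ("A", "C", "G", "T")

COUNT_COLUMNS = ["mag_id", "contig_id", "position", "sample_id", "A", "C", "G", "T"]


def configure_logging(level: str = "INFO") -> None:
    """Line-oriented, timestamped logging for every CLI subcommand."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


def log_filter(name: str, before: int, after: int) -> None:
    """Report a filter application with counts before/after (shared convention)."""
    logger.info("filter %s: %d -> %d rows", name, before, after)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleRecord:
    """One metagenome sample placed in the site x core x horizon design."""

    sample_id: str
    site_id: str
    trench_system: str
    realm: str
    water_depth_m: float
    core_id: str
    horizon_top_cm: float
    horizon_bottom_cm: float
    geochem_zone: str

    @property
    def horizon(self) -> str:
        """Depth-interval label such as ``'0-1'`` (cm below seafloor)."""
        return f"{self.horizon_top_cm:g}-{self.horizon_bottom_cm:g}"

    def validate(self) -> None:
        if self.trench_system not in TRENCH_SYSTEMS:
            raise ValidationError(
                f"sample {self.sample_id}: unknown trench_system {self.trench_system!r}"
            )
        if self.realm not in REALMS:
            raise ValidationError(f"sample {self.sample_id}: unknown realm {self.realm!r}")
        if self.geochem_zone not in GEOCHEM_ZONES:
            raise ValidationError(
                f"sample {self.sample_id}: unknown geochem_zone {self.geochem_zone!r}"
            )
        if not self.water_depth_m > 0:
            raise ValidationError(f"sample {self.sample_id}: water_depth_m must be positive")
        if not self.horizon_bottom_cm > self.horizon_top_cm >= 0:
            raise ValidationError(
                f"sample {self.sample_id}: bad horizon interval "
                f"[{self.horizon_top_cm}, {self.horizon_bottom_cm}]"
            )


METADATA_COLUMNS = [
    "sample_id",
    "site_id",
    "trench_system",
    "realm",
    "water_depth_m",
    "core_id",
    "horizon_top_cm",
    "horizon_bottom_cm",
    "geochem_zone",
]


def validate_sample_records(records: Sequence[SampleRecord]) -> None:
    """Check cross-record invariants: unique keys, non-overlapping horizons."""
    seen_ids = set()
    seen_triples = set()
    for rec in records:
        rec.validate()
        if rec.sample_id in seen_ids:
            raise ValidationError(f"duplicate sample_id {rec.sample_id!r}")
        seen_ids.add(rec.sample_id)
        triple = (rec.site_id, rec.core_id, rec.horizon)
        if triple in seen_triples:
            raise ValidationError(f"duplicate (site, core, horizon) triple {triple}")
        seen_triples.add(triple)
    # horizons within one core must not overlap
    by_core: dict[tuple[str, str], list[SampleRecord]] = {}
    for rec in records:
        by_core.setdefault((rec.site_id, rec.core_id), []).append(rec)
    for (site, core), recs in by_core.items():
        recs = sorted(recs, key=lambda r: r.horizon_top_cm)
        for a, b in zip(recs, recs[1:]):
            if b.horizon_top_cm < a.horizon_bottom_cm:
                raise ValidationError(
                    f"overlapping horizons in core {site}/{core}: "
                    f"{a.horizon} and {b.horizon}"
                )


def read_sample_metadata(path) -> list[SampleRecord]:
    """Read the sample metadata TSV and validate the sampling design."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"sample metadata {path}: missing required column {col!r}")
    records = [
        SampleRecord(
            sample_id=row.sample_id,
            site_id=row.site_id,
            trench_system=row.trench_system,
            realm=row.realm,
            water_depth_m=float(row.water_depth_m),
            core_id=row.core_id,
            horizon_top_cm=float(row.horizon_top_cm),
            horizon_bottom_cm=float(row.horizon_bottom_cm),
            geochem_zone=row.geochem_zone,
        )
        for row in df.itertuples(index=False)
    ]
    validate_sample_records(records)
    return records


def write_sample_metadata(records: Sequence[SampleRecord], path) -> None:
    df = pd.DataFrame([asdict(r) for r in records], columns=METADATA_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# base-count ("variability") tables
# ---------------------------------------------------------------------------

_ANVIO_RENAME = {"split_name": "contig_id", "pos": "position"}


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a BaseCountTable DataFrame; returns it with canonical dtypes."""
    for col in COUNT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"base-count table: missing required column {col!r}")
    df = df[COUNT_COLUMNS].copy()
    for base in BASES:
        counts = pd.to_numeric(df[base])
        bad = np.flatnonzero(counts.to_numpy() < 0)
        if bad.size:
            raise ValidationError(
                f"negative count in column {base!r} at row {int(bad[0])}"
            )
        df[base] = counts.astype(np.int64)
    df["position"] = pd.to_numeric(df["position"]).astype(np.int64)
    if (df["position"] < 0).any():
        raise ValidationError("negative position in base-count table")
    key = ["mag_id", "contig_id", "position", "sample_id"]
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key, keep=False)].iloc[0]
        raise ValidationError(
            "duplicate row for (mag, contig, position, sample) = "
            f"({dup.mag_id}, {dup.contig_id}, {dup.position}, {dup.sample_id})"
        )
    return df


def read_variability_table(path, dialect: str = "native", mag_id: str | None = None) -> pd.DataFrame:
    """Read a per-position nucleotide count table.

    Parameters
    ----------
    path
        TSV file with a header row.
    dialect
        ``"native"`` expects columns mag_id, contig_id, position, sample_id,
        A, C, G, T. ``"anvio"`` maps sample_id, split_name, pos, A, C, G, T;
        split_name doubles as contig_id, and mag_id is taken from a column of
        that name or from the ``mag_id`` argument.
    mag_id
        MAG identifier for anvio-dialect files lacking a mag_id column.

    Returns a validated BaseCountTable DataFrame (one row per
    (mag, contig, position, sample); columns A/C/G/T are read counts).
    An ``N`` column, if present, is ignored: coverage counts only reads
    supporting an unambiguous call.
    """
    if dialect not in ("native", "anvio"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    if dialect == "anvio":
        for col in ("sample_id", "split_name", "pos", "A", "C", "G", "T"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column {col!r} (anvio dialect)")
        df = df.rename(columns=_ANVIO_RENAME)
        if "mag_id" not in df.columns:
            if mag_id is None:
                raise FormatError(
                    f"{path}: anvio dialect needs a mag_id column or the mag_id argument"
                )
            df["mag_id"] = mag_id
    extra = [c for c in df.columns if c not in COUNT_COLUMNS]
    if extra:
        logger.info("read_variability_table %s: ignoring extra columns %s", path, extra)
    if df.empty:
        # header-only file: build an empty, well-typed table
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in COUNT_COLUMNS})
        for base in BASES:
            df[base] = df[base].astype(np.int64)
        df["position"] = df["position"].astype(np.int64)
        return df
    return validate_counts(df)


def write_variability_table(df: pd.DataFrame, path) -> None:
    """Write a BaseCountTable in the native dialect (0-based positions)."""
    validate_counts(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# distance matrices and trees
# ---------------------------------------------------------------------------


def write_distance_matrix(matrix, path) -> None:
    """Write an FstMatrix as a square TSV (sample ids as header and first column).

    Values are written with 17 significant digits so the round trip is exact
    to well beyond 12 significant digits.
    """
    values = np.asarray(matrix.values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(values, values.T, rtol=0, atol=0, equal_nan=True):
        raise ValidationError("distance matrix must be symmetric")
    if not np.all(np.diag(values) == 0):
        raise ValidationError("distance matrix must have a zero diagonal")
    ids = list(matrix.sample_ids)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(ids) + "\n")
        for sid, row in zip(ids, values):
            fh.write(sid + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


def read_distance_matrix(path):
    """Read a square distance-matrix TSV back into an FstMatrix.

    Columns are joined to rows by label, so a file whose row and column
    orders differ is reordered to row order with values preserved.
    """
    from .fst import FstMatrix  # local import: fst does not import io

    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    ids = [str(i) for i in df.index]
    if sorted(ids) != sorted(str(c) for c in df.columns):
        raise FormatError(f"{path}: row and column labels differ")
    df.columns = [str(c) for c in df.columns]
    df = df.loc[ids, ids]
    return FstMatrix(sample_ids=ids, values=df.to_numpy(dtype=float))


def write_newick(tree, path) -> None:
    """Export a dendrogram to a Newick file.

    ``tree`` is a :class:`magpop.fst.Dendrogram`. Leaf labels must be unique
    and the tree non-empty.
    """
    labels = list(tree.labels)
    if not labels:
        raise ValidationError("cannot write an empty tree")
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate leaf labels in dendrogram")
    newick = tree.to_newick()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(newick + "\n")


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All analysis thresholds in one auditable place.

    Defaults follow the study conventions: positions are reported at >= 10x
    coverage in every sample considered and >= 0.1 departure from consensus;
    MAG mean coverage is used as a relative-abundance proxy only when
    detection (breadth of coverage) exceeds 0.7; MAGs enter the per-MAG
    analysis when covered >= 10x in at least 40 samples, or 20 samples as
    the fallback for sparsely-detected (abyssal) lineages.
    """

    min_coverage: int = 10
    min_departure: float = 0.1
    min_detection: float = 0.7
    min_samples_main: int = 40
    min_samples_abyssal: int = 20
    site_set: str = "snv-union"          # or "all-covered"
    density_denominator: str = "core-positions"  # or "mag-length"
    shared_denominator: str = "union"    # or "min", "mean"
    n_permutations: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"config {path}: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def override(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given (non-None) fields replaced."""
        data = asdict(self)
        for key, value in kwargs.items():
            if value is not None:
                if key not in data:
                    raise ValueError(f"unknown config field {key!r}")
                data[key] = value
        return PipelineConfig(**data)
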