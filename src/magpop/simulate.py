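"""Forward simulator for stratified-sediment metagenome variability profiles.

The generator emulates the statistical structure the analysis assumes:

* a hierarchical sampling design (realm -> trench system -> site -> replicate
  core -> sediment horizon) mirroring a two-trench deep-sea cruise: six sites
  (K6, K7, A3 x3 cores, A7 x3 cores, A9, A10), horizons 0-1, 1-3, 3-5, 5-10,
  10-15 and 15-30 cm, and an oxic/nitrogenous/ferruginous zonation;
* neutral population divergence along that hierarchy via the Balding-Nichols
  model: given a parent allele frequency p and a divergence parameter F, a
  daughter deme's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), so the expected
  fixation index between two daughters equals F;
* niche-dependent convergent selection: each MAG has an optimal horizon, and
  every cell's frequency is pulled toward the MAG's per-site optimal allele
  (the derived, initially-minor allele) by a factor s * w(horizon), where
  w = exp(-|rank(h) - rank(h_opt)| / tau) peaks at 1 on the optimal horizon;
* depth-dependent abundance: mean coverage lambda(horizon) follows the same
  peaked profile, coupling coverage to niche;
* finite-coverage read sampling: per-position depth ~ Poisson(lambda), base
  calls ~ Multinomial with per-base error epsilon spread uniformly over the
  other three bases.

Variable sites are biallelic; tri-allelic observations arise only through
sequencing error. Monomorphic positions are not emitted per-position: they
enter only the aggregate coverage/detection summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .io import BASES, SampleRecord, validate_sample_records

BASE_INDEX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class Horizon:
    top_cm: float
    bottom_cm: float
    zone: str

    @property
    def label(self) -> str:
        return f"{self.top_cm:g}-{self.bottom_cm:g}"


def standard_horizons(realm: str) -> list[Horizon]:
    """The cruise slicing scheme with a realm-dependent redox zonation.

    Oxygen persists decimeters down in abyssal sediments but only a few
    centimeters in hadal ones, so the oxic zone is thicker at abyssal sites.
    """
    depths = [(0, 1), (1, 3), (3, 5), (5, 10), (10, 15), (15, 30)]
    if realm == "abyssal":
        zones = ["oxic", "oxic", "oxic", "nitrogenous", "nitrogenous", "ferruginous"]
    else:
        zones = ["oxic", "oxic", "nitrogenous", "nitrogenous", "ferruginous", "ferruginous"]
    return [Horizon(t, b, z) for (t, b), z in zip(depths, zones)]


@dataclass
class SiteSpec:
    site_id: str
    trench_system: str
    realm: str
    water_depth_m: float
    n_cores: int = 1
    horizons: list[Horizon] | None = None

    def __post_init__(self):
        if self.horizons is None:
            self.horizons = standard_horizons(self.realm)
        if self.n_cores < 1:
            raise ValidationError(f"site {self.site_id}: n_cores must be >= 1")


@dataclass
class MagSpec:
    """Per-MAG population parameters.

    Divergence parameters f_realm/f_trench/f_site/f_core are Balding-Nichols
    F values in [0, 1) for each hierarchy level (0 copies the parent).
    ``selection_strength`` s in [0, 1] pulls cell frequencies toward the
    per-site optimal allele at the optimal horizon; ``tau`` sets how fast the
    pull decays with horizon-rank distance. ``coverage_peak``/``coverage_floor``
    define the peaked abundance profile lambda(horizon) aligned with the
    optimal horizon. ``error_rate`` is the per-read-base error epsilon.
    """

    mag_id: str
    genome_length_bp: int = 100_000
    n_variable_sites: int = 1_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    f_realm: float = 0.1
    f_trench: float = 0.05
    f_site: float = 0.02
    f_core: float = 0.0
    selection_strength: float = 0.0
    optimal_horizon: int = 0
    tau: float = 1.0
    coverage_peak: float = 50.0
    coverage_floor: float = 10.0
    error_rate: float = 0.001

    def validate(self) -> None:
        if not 0 < self.n_variable_sites <= self.genome_length_bp:
            raise ValidationError(
                f"MAG {self.mag_id}: need 0 < n_variable_sites <= genome_length_bp"
            )
        for name in ("f_realm", "f_trench", "f_site", "f_core"):
            f = getattr(self, name)
            if not 0 <= f < 1:
                raise ValidationError(f"MAG {self.mag_id}: {name} must be in [0, 1)")
        if not 0 <= self.selection_strength <= 1:
            raise ValidationError(f"MAG {self.mag_id}: selection_strength must be in [0, 1]")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValidationError(f"MAG {self.mag_id}: need 0 < maf_low <= maf_high <= 0.5")
        if self.coverage_peak < 0 or self.coverage_floor < 0:
            raise ValidationError(f"MAG {self.mag_id}: coverage must be non-negative")
        if not 0 <= self.error_rate < 0.25:
            raise ValidationError(f"MAG {self.mag_id}: error_rate must be in [0, 0.25)")
        if self.tau <= 0:
            raise ValidationError(f"MAG {self.mag_id}: tau must be positive")

    def coverage_profile(self, n_horizons: int) -> np.ndarray:
        """lambda(horizon): peaked at the optimal horizon, decaying with rank distance."""
        ranks = np.arange(n_horizons)
        w = np.exp(-np.abs(ranks - self.optimal_horizon) / self.tau)
        return self.coverage_floor + (self.coverage_peak - self.coverage_floor) * w

    def selection_weight(self, n_horizons: int) -> np.ndarray:
        ranks = np.arange(n_horizons)
        return np.exp(-np.abs(ranks - self.optimal_horizon) / self.tau)


def default_sites() -> list[SiteSpec]:
    """The two-trench cruise design: 10 cores, 60 samples."""
    return [
        SiteSpec("K6", "Kermadec", "hadal", 9555.0, n_cores=1),
        SiteSpec("K7", "Kermadec", "abyssal", 6080.0, n_cores=1),
        SiteSpec("A3", "Atacama", "hadal", 7915.0, n_cores=3),
        SiteSpec("A7", "Atacama", "abyssal", 5500.0, n_cores=3),
        SiteSpec("A9", "Atacama", "abyssal", 4050.0, n_cores=1),
        SiteSpec("A10", "Atacama", "hadal", 7770.0, n_cores=1),
    ]


def default_mags() -> list[MagSpec]:
    """Four MAGs whose niches mirror the main lineages' depth preferences:

    two surface-adapted populations (optimal horizon 0-1 cm), one mid-depth
    (1-3 cm) and one deep-adapted (5-10 cm), with abundance coupled to niche.
    Divergence defaults (realm 0.1 > trench 0.05 > site 0.02 > core 0) give
    the strongest neutral structure at the realm level; moderate convergent
    selection (s = 0.5) produces the downcore inter-core signature.
    """
    common = dict(
        genome_length_bp=100_000,
        n_variable_sites=1_000,
        selection_strength=0.5,
        coverage_peak=60.0,
        coverage_floor=3.0,
    )
    return [
        MagSpec(mag_id="MAG_surface_1", optimal_horizon=0, **common),
        MagSpec(mag_id="MAG_surface_2", optimal_horizon=0, **common),
        MagSpec(mag_id="MAG_mid", optimal_horizon=1, **common),
        MagSpec(mag_id="MAG_deep", optimal_horizon=3, **common),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    sites: list[SiteSpec] = field(default_factory=default_sites)
    mags: list[MagSpec] = field(default_factory=default_mags)

    def validate(self) -> None:
        if not self.sites or not self.mags:
            raise ValidationError("config needs at least one site and one MAG")
        n_horizons = {len(s.horizons) for s in self.sites}
        for mag in self.mags:
            mag.validate()
            if any(mag.optimal_horizon >= n for n in n_horizons):
                raise ValidationError(
                    f"MAG {mag.mag_id}: optimal_horizon beyond the horizon list"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        sites = [
            SiteSpec(
                **{**s, "horizons": [Horizon(**h) for h in s["horizons"]] if s.get("horizons") else None}
            )
            for s in data.get("sites", [])
        ] or default_sites()
        mags = [MagSpec(**m) for m in data.get("mags", [])] or default_mags()
        return cls(seed=int(data.get("seed", 0)), sites=sites, mags=mags)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def sample_records(self) -> list[SampleRecord]:
        records = []
        for site in self.sites:
            for c in range(1, site.n_cores + 1):
                core_id = f"c{c}"
                for hz in site.horizons:
                    records.append(
                        SampleRecord(
                            sample_id=f"{site.site_id}_{core_id}_{hz.top_cm:g}_{hz.bottom_cm:g}",
                            site_id=site.site_id,
                            trench_system=site.trench_system,
                            realm=site.realm,
                            water_depth_m=site.water_depth_m,
                            core_id=core_id,
                            horizon_top_cm=hz.top_cm,
                            horizon_bottom_cm=hz.bottom_cm,
                            geochem_zone=hz.zone,
                        )
                    )
        validate_sample_records(records)
        return records


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------


@dataclass
class MagTruth:
    """Hidden allele-frequency field for one MAG.

    Sites are biallelic: ``major_idx``/``minor_idx`` are base indices into
    A, C, G, T; all stored frequencies are minor-allele frequencies. The
    minor (derived) allele is the selective optimum at the MAG's niche.
    ``cell_freq[(site_id, core_id, horizon_rank)]`` is the realized
    frequency field of one sample cell; ``lambda_by_rank`` its mean coverage.
    """

    mag_id: str
    contig_id: str
    positions: np.ndarray
    major_idx: np.ndarray
    minor_idx: np.ndarray
    ancestral_freq: np.ndarray
    deme_freq: dict
    cell_freq: dict
    lambda_by_rank: np.ndarray

    def frequency_vectors(self, site_id: str, core_id: str, rank: int) -> np.ndarray:
        """(n_sites, 4) simplex vectors for one cell."""
        minor = self.cell_freq[(site_id, core_id, rank)]
        out = np.zeros((minor.size, 4), dtype=float)
        out[np.arange(minor.size), self.minor_idx] = minor
        out[np.arange(minor.size), self.major_idx] += 1.0 - minor
        return out


@dataclass
class SimulationTruth:
    config: SimulationConfig
    samples: list[SampleRecord]
    mags: dict[str, MagTruth]


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Daughter-deme frequencies given parent frequencies p and divergence F."""
    if f == 0:
        return p.copy()
    out = p.copy()
    free = (p > 0) & (p < 1)  # fixed sites stay fixed
    a = p[free] * (1 - f) / f
    b = (1 - p[free]) * (1 - f) / f
    out[free] = rng.beta(a, b)
    return out


def _freq_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))


def _count_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))


def simulate_frequencies(config: SimulationConfig) -> SimulationTruth:
    """Draw the hidden allele-frequency hierarchy for every MAG and cell.

    For each variable site an ancestral minor-allele frequency is drawn
    uniformly from [maf_low, maf_high] with the two segregating bases drawn
    uniformly without replacement from {A, C, G, T}. Frequencies then cascade
    realm -> trench -> site -> core through Balding-Nichols draws, and each
    cell (core x horizon) frequency is shifted toward the optimal (minor)
    allele by s * w(horizon). All draws are governed by the config seed.
    """
    config.validate()
    rng = _freq_rng(config.seed)
    samples = config.sample_records()

    realms = sorted({s.realm for s in config.sites})
    trenches = sorted({(s.realm, s.trench_system) for s in config.sites})
    sites = list(config.sites)

    mags: dict[str, MagTruth] = {}
    for mag in config.mags:
        n = mag.n_variable_sites
        positions = np.sort(rng.choice(mag.genome_length_bp, size=n, replace=False))
        # biallelic: draw an ordered pair of distinct bases per site
        major_idx = rng.integers(0, 4, size=n)
        minor_off = rng.integers(1, 4, size=n)
        minor_idx = (major_idx + minor_off) % 4
        ancestral = rng.uniform(mag.maf_low, mag.maf_high, size=n)

        deme_freq: dict = {}
        for realm in realms:
            deme_freq[("realm", realm)] = _balding_nichols(rng, ancestral, mag.f_realm)
        for realm, trench in trenches:
            deme_freq[("trench", realm, trench)] = _balding_nichols(
                rng, deme_freq[("realm", realm)], mag.f_trench
            )
        for site in sites:
            deme_freq[("site", site.site_id)] = _balding_nichols(
                rng, deme_freq[("trench", site.realm, site.trench_system)], mag.f_site
            )

        cell_freq: dict = {}
        for site in sites:
            n_horizons = len(site.horizons)
            weight = mag.selection_weight(n_horizons)
            for c in range(1, site.n_cores + 1):
                core_id = f"c{c}"
                core = _balding_nichols(rng, deme_freq[("site", site.site_id)], mag.f_core)
                deme_freq[("core", site.site_id, core_id)] = core
                for rank in range(n_horizons):
                    sw = mag.selection_strength * weight[rank]
                    # pull toward the optimal (minor) allele
                    cell_freq[(site.site_id, core_id, rank)] = (1.0 - sw) * core + sw

        n_horizons = max(len(s.horizons) for s in sites)
        mags[mag.mag_id] = MagTruth(
            mag_id=mag.mag_id,
            contig_id=f"{mag.mag_id}_contig_0001",
            positions=positions,
            major_idx=major_idx,
            minor_idx=minor_idx,
            ancestral_freq=ancestral,
            deme_freq=deme_freq,
            cell_freq=cell_freq,
            lambda_by_rank=mag.coverage_profile(n_horizons),
        )
    return SimulationTruth(config=config, samples=samples, mags=mags)


def multinomial_rows(rng: np.random.Generator, depth: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Row-wise multinomial draws via conditional binomials (vectorized)."""
    k, categories = probs.shape
    counts = np.zeros((k, categories), dtype=np.int64)
    remaining = depth.astype(np.int64).copy()
    rem_p = np.ones(k, dtype=float)
    for j in range(categories - 1):
        with np.errstate(invalid="ignore", divide="ignore"):
            pj = np.where(rem_p > 1e-12, np.clip(probs[:, j] / rem_p, 0.0, 1.0), 0.0)
        c = rng.binomial(remaining, pj)
        counts[:, j] = c
        remaining -= c
        rem_p -= probs[:, j]
    counts[:, categories - 1] = remaining
    return counts


def perturb_by_error(freqs: np.ndarray, epsilon: float) -> np.ndarray:
    """Read-level error: each true base is misread as one of the other three
    with total probability epsilon, spread uniformly."""
    return freqs * (1.0 - epsilon) + (epsilon / 3.0) * (1.0 - freqs)


def simulate_cell_counts(
    rng: np.random.Generator, freq_vectors: np.ndarray, lam: float, epsilon: float
) -> np.ndarray:
    """(n_sites, 4) read counts for one cell at mean coverage lambda."""
    n = freq_vectors.shape[0]
    depth = rng.poisson(lam, size=n)
    probs = perturb_by_error(freq_vectors, epsilon)
    return multinomial_rows(rng, depth, probs)


def simulate_counts(truth: SimulationTruth, config: SimulationConfig | None = None):
    """Sample read counts and coverage summaries from a frequency truth.

    Returns ``(counts, coverage)``: a BaseCountTable DataFrame over variable
    positions with depth > 0, and a CoverageSummary DataFrame whose
    mean_coverage/detection include the monomorphic remainder of each genome
    in aggregate (total depth ~ Poisson, presence ~ Bernoulli per position).
    Deterministic given the config seed.
    """
    config = config or truth.config
    rng = _count_rng(config.seed)
    mag_specs = {m.mag_id: m for m in config.mags}
    sites = {s.site_id: s for s in config.sites}

    count_rows = []
    cov_rows = []
    for mag_id, mt in truth.mags.items():
        spec = mag_specs[mag_id]
        for rec in truth.samples:
            site = sites[rec.site_id]
            rank = next(
                i for i, hz in enumerate(site.horizons) if hz.label == rec.horizon
            )
            lam = float(mt.lambda_by_rank[rank])
            freq_vectors = mt.frequency_vectors(rec.site_id, rec.core_id, rank)
            counts = simulate_cell_counts(rng, freq_vectors, lam, spec.error_rate)
            depth = counts.sum(axis=1)
            nonzero = np.flatnonzero(depth)
            for idx in nonzero:
                count_rows.append(
                    (
                        mag_id,
                        mt.contig_id,
                        int(mt.positions[idx]),
                        rec.sample_id,
                        int(counts[idx, 0]),
                        int(counts[idx, 1]),
                        int(counts[idx, 2]),
                        int(counts[idx, 3]),
                    )
                )
            # aggregate coverage over the full genome, monomorphic positions included
            length = spec.genome_length_bp
            n_rest = length - mt.positions.size
            total_depth = int(depth.sum()) + int(rng.poisson(lam * n_rest)) if lam > 0 else 0
            p_present = 1.0 - np.exp(-lam)
            detected = int(nonzero.size) + (
                int(rng.binomial(n_rest, p_present)) if lam > 0 else 0
            )
            mean_cov = total_depth / length
            detection = detected / length
            cov_rows.append(
                {
                    "mag_id": mag_id,
                    "sample_id": rec.sample_id,
                    "mean_coverage": mean_cov,
                    "detection": detection,
                    "reported_coverage": mean_cov if detection > 0.7 else 0.0,
                }
            )
    counts_df = pd.DataFrame(
        count_rows,
        columns=["mag_id", "contig_id", "position", "sample_id", "A", "C", "G", "T"],
    )
    coverage_df = pd.DataFrame(
        cov_rows,
        columns=["mag_id", "sample_id", "mean_coverage", "detection", "reported_coverage"],
    )
    return counts_df, coverage_df


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------


def truth_table(truth: SimulationTruth) -> pd.DataFrame:
    """Flatten the hidden frequency field into a TSV-ready table."""
    sites = {s.site_id: s for s in truth.config.sites}
    rows = []
    for mag_id, mt in truth.mags.items():
        for (site_id, core_id, rank), minor in sorted(mt.cell_freq.items()):
            hz = sites[site_id].horizons[rank]
            vecs = mt.frequency_vectors(site_id, core_id, rank)
            for idx in range(mt.positions.size):
                rows.append(
                    (
                        mag_id,
                        site_id,
                        core_id,
                        hz.label,
                        mt.contig_id,
                        int(mt.positions[idx]),
                        *[float(v) for v in vecs[idx]],
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "mag_id",
            "site_id",
            "core_id",
            "horizon",
            "contig_id",
            "position",
            "freq_A",
            "freq_C",
            "freq_G",
            "freq_T",
        ],
    )


def reference_fasta(truth: SimulationTruth, rng: np.random.Generator | None = None):
    """Random reference sequences with ancestral (major) alleles embedded."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = rng or np.random.default_rng(
        np.random.SeedSequence(entropy=truth.config.seed, spawn_key=(2,))
    )
    specs = {m.mag_id: m for m in truth.config.mags}
    records = []
    for mag_id, mt in truth.mags.items():
        length = specs[mag_id].genome_length_bp
        seq = rng.integers(0, 4, size=length)
        seq[mt.positions] = mt.major_idx
        letters = np.array(list("ACGT"))
        records.append(
            SeqRecord(Seq("".join(letters[seq])), id=mt.contig_id, description="synthetic")
        )
    return records


def write_truth_bundle(truth: SimulationTruth, counts: pd.DataFrame, coverage: pd.DataFrame, outdir) -> dict:
    """Write the full simulated bundle; returns {name: path}.

    Emits native-dialect counts, coverage, sample metadata, the truth table,
    a reference FASTA and the echoed config. Re-reading the counts and
    metadata reproduces the inputs exactly.
    """
    from Bio import SeqIO

    from .io import write_sample_metadata, write_variability_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "coverage": outdir / "coverage.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
        "fasta": outdir / "reference.fasta",
        "config": outdir / "config.yaml",
    }
    write_variability_table(counts, paths["counts"])
    coverage.to_csv(paths["coverage"], sep="\t", index=False, float_format="%.10g")
    write_sample_metadata(truth.samples, paths["metadata"])
    truth_table(truth).to_csv(paths["truth"], sep="\t", index=False, float_format="%.17g")
    with open(paths["fasta"], "w", encoding="utf-8") as fh:
        SeqIO.write(reference_fasta(truth), fh, "fasta")
    truth.config.to_yaml(paths["config"])
    return {k: str(v) for k, v in paths.items()}


def simulate_bundle(config: SimulationConfig):
    """Convenience: frequencies + counts in one call."""
    truth = simulate_frequencies(config)
    counts, coverage = simulate_counts(truth, config)
    return truth, counts, coverage
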