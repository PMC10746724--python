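"""Simulation-based validation experiments for the estimators.

Each function runs the generator at fixed, documented conditions and measures
how well an estimator recovers the configured truth. They back both the test
suite and the reproducibility script, so the numbers they return are always
recomputed from scratch.

Conditions (chosen once, as the study design the generator emulates):

* F_ST recovery: two demes diverged at a single hierarchy level, 10^4
  biallelic sites, 50x mean coverage — the Balding-Nichols moment identity
  E[F_ST] = F holds over *all* segregating sites, so the recovery experiment
  evaluates the estimator on every covered site rather than on the
  SNV-ascertained subset (ascertainment is a property of real-data
  reporting, not of the identity).
* Null calibration: panmictic samples at 100x / 5,000 sites for the F_ST
  magnitude check, and many small panmictic replicates for the PERMANOVA
  type-I error.
* Structure recovery: realm-level divergence 0.1 over site-level 0.02,
  drift only, flat coverage.
* Niche signature: one site with replicate cores drifting at F_core = 0.05,
  convergent selection s pulling all cores toward the same optimum at one
  horizon, abundance peaked on that horizon.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fst import fst_matrix, pairwise_fst_from_arrays, ward_cluster
from .permanova import permanova
from .shared import build_pair_comparisons, fit_fst_regressions, horizon_summary, intercore_vs_intracore_test
from .simulate import (
    Horizon,
    MagSpec,
    SimulationConfig,
    SiteSpec,
    simulate_bundle,
    simulate_cell_counts,
    simulate_frequencies,
    _count_rng,
)
from .snv import call_snvs


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible sub-seeds below 2^31 derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _single_horizon() -> list[Horizon]:
    return [Horizon(0, 1, "oxic")]


def _two_deme_config(f: float, n_sites: int, coverage: float, seed: int) -> SimulationConfig:
    """Two site-level demes, drift only, flat coverage, one sample each."""
    mag = MagSpec(
        mag_id="MAG_sim",
        genome_length_bp=2 * n_sites,
        n_variable_sites=n_sites,
        f_realm=0.0,
        f_trench=0.0,
        f_site=f,
        f_core=0.0,
        selection_strength=0.0,
        coverage_peak=coverage,
        coverage_floor=coverage,
        error_rate=0.001,
    )
    sites = [
        SiteSpec("S1", "Atacama", "abyssal", 5000.0, n_cores=1, horizons=_single_horizon()),
        SiteSpec("S2", "Atacama", "abyssal", 5000.0, n_cores=1, horizons=_single_horizon()),
    ]
    return SimulationConfig(seed=seed, sites=sites, mags=[mag])


def fst_recovery(
    f_values=(0.05, 0.1, 0.2, 0.4),
    n_sites: int = 10_000,
    coverage: float = 50.0,
    seed: int = 0,
) -> dict[float, float]:
    """Estimated between-deme F_ST for each configured divergence F.

    Runs the full pipeline path (simulate -> counts -> F_ST matrix) with the
    all-covered site policy, under which the Balding-Nichols expectation
    E[F_ST] = F applies.
    """
    seeds = _child_seeds(seed, len(f_values))
    out = {}
    for f, sub_seed in zip(f_values, seeds):
        config = _two_deme_config(f, n_sites, coverage, int(sub_seed))
        truth, counts, _ = simulate_bundle(config)
        snvs = call_snvs(counts, min_coverage=10, min_departure=0.1)
        sample_ids = sorted(counts["sample_id"].unique())
        matrix = fst_matrix(
            counts, snvs, sample_ids, min_coverage=10, site_set="all-covered"
        )
        out[f] = float(matrix.values[0, 1])
    return out


def null_fst(
    n_sites: int = 5_000,
    coverage: float = 100.0,
    n_samples: int = 2,
    seed: int = 0,
) -> float:
    """Max |pairwise F_ST| among samples drawn from one panmictic population."""
    mag = MagSpec(
        mag_id="MAG_sim",
        genome_length_bp=2 * n_sites,
        n_variable_sites=n_sites,
        f_realm=0.0,
        f_trench=0.0,
        f_site=0.0,
        f_core=0.0,
        selection_strength=0.0,
        coverage_peak=coverage,
        coverage_floor=coverage,
        error_rate=0.001,
    )
    sites = [
        SiteSpec("S1", "Atacama", "abyssal", 5000.0, n_cores=n_samples, horizons=_single_horizon())
    ]
    config = SimulationConfig(seed=seed, sites=sites, mags=[mag])
    truth, counts, _ = simulate_bundle(config)
    snvs = call_snvs(counts, min_coverage=10, min_departure=0.1)
    sample_ids = sorted(counts["sample_id"].unique())
    matrix = fst_matrix(counts, snvs, sample_ids, min_coverage=10, site_set="snv-union")
    off_diag = matrix.values[np.triu_indices(len(sample_ids), k=1)]
    return float(np.nanmax(np.abs(off_diag)))


def permanova_type1_error(
    n_replicates: int = 1_000,
    n_samples: int = 16,
    n_sites: int = 300,
    coverage: float = 50.0,
    n_permutations: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of PERMANOVA on panmictic F_ST matrices.

    Each replicate draws ``n_samples`` read-count profiles from one
    population (identical true frequencies), computes the pairwise F_ST
    matrix and tests an arbitrary half/half grouping. Under the null the
    labels are exchangeable, so the rejection rate at level alpha should sit
    near alpha. Uses the same estimator cores as the pipeline, with the
    DataFrame plumbing bypassed for speed.

    ``n_samples`` must be large enough that the half/half partition space
    dwarfs ``n_permutations``: with few samples (e.g. 10, giving only
    C(10,5) = 252 distinct partitions) sampled permutations tie the observed
    statistic often enough to bias the measured level visibly below alpha.
    The default 16 gives C(16,8) = 12,870 partitions, making ties negligible.
    """
    labels = ["g1"] * (n_samples // 2) + ["g2"] * (n_samples - n_samples // 2)
    seeds = _child_seeds(seed, 2 * n_replicates)
    rejections = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(int(seeds[2 * r]))
        p = rng.uniform(0.05, 0.5, size=n_sites)
        major = rng.integers(0, 4, size=n_sites)
        minor = (major + rng.integers(1, 4, size=n_sites)) % 4
        freq_vectors = np.zeros((n_sites, 4))
        freq_vectors[np.arange(n_sites), minor] = p
        freq_vectors[np.arange(n_sites), major] += 1.0 - p
        counts = np.stack(
            [simulate_cell_counts(rng, freq_vectors, coverage, 0.001) for _ in range(n_samples)]
        )
        cov = counts.sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = np.where(cov[..., None] > 0, counts / np.maximum(cov[..., None], 1), 0.0)
        departure = 1.0 - freqs.max(axis=-1)
        snv_mask = (cov >= 10) & (departure >= 0.1)
        values, _ = pairwise_fst_from_arrays(freqs, cov, snv_mask, min_coverage=10)
        if np.isnan(values).any():
            continue  # a pair with no usable sites cannot be tested; does not occur at these depths
        res = permanova(values, labels, n_permutations=n_permutations, seed=int(seeds[2 * r + 1]))
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_replicates


def _hierarchical_config(
    f_realm: float, f_site: float, n_sites: int, coverage: float, seed: int
) -> SimulationConfig:
    """Two realms x two sites x three horizons, drift only, flat coverage."""
    horizons = [Horizon(0, 1, "oxic"), Horizon(1, 3, "oxic"), Horizon(3, 5, "nitrogenous")]
    mag = MagSpec(
        mag_id="MAG_sim",
        genome_length_bp=2 * n_sites,
        n_variable_sites=n_sites,
        f_realm=f_realm,
        f_trench=0.0,
        f_site=f_site,
        f_core=0.0,
        selection_strength=0.0,
        coverage_peak=coverage,
        coverage_floor=coverage,
        error_rate=0.001,
    )
    sites = [
        SiteSpec("H1", "Atacama", "hadal", 8000.0, n_cores=1, horizons=list(horizons)),
        SiteSpec("H2", "Kermadec", "hadal", 9000.0, n_cores=1, horizons=list(horizons)),
        SiteSpec("B1", "Atacama", "abyssal", 5000.0, n_cores=1, horizons=list(horizons)),
        SiteSpec("B2", "Kermadec", "abyssal", 6000.0, n_cores=1, horizons=list(horizons)),
    ]
    return SimulationConfig(seed=seed, sites=sites, mags=[mag])


def realm_split_recovery(
    n_replicates: int = 20,
    f_realm: float = 0.1,
    f_site: float = 0.02,
    n_sites: int = 1_500,
    coverage: float = 50.0,
    seed: int = 0,
) -> int:
    """How many replicates' Ward dendrograms split first by ocean realm.

    Returns the number of replicates (out of ``n_replicates``) in which the
    first bipartition of the Ward tree equals the abyssal/hadal partition.
    """
    seeds = _child_seeds(seed, n_replicates)
    successes = 0
    for sub_seed in seeds:
        config = _hierarchical_config(f_realm, f_site, n_sites, coverage, int(sub_seed))
        truth, counts, _ = simulate_bundle(config)
        snvs = call_snvs(counts, min_coverage=10, min_departure=0.1)
        sample_ids = sorted(counts["sample_id"].unique())
        matrix = fst_matrix(counts, snvs, sample_ids, min_coverage=10)
        tree = ward_cluster(matrix)
        side_a, side_b = tree.first_bipartition()
        realm_of = {rec.sample_id: rec.realm for rec in truth.samples}
        realms_a = {realm_of[s] for s in side_a}
        realms_b = {realm_of[s] for s in side_b}
        if len(realms_a) == 1 and len(realms_b) == 1 and realms_a != realms_b:
            successes += 1
    return successes


def niche_config(
    s: float = 0.6,
    optimal_rank: int = 2,
    f_core: float = 0.05,
    n_sites: int = 800,
    coverage_peak: float = 60.0,
    coverage_floor: float = 15.0,
    tau: float = 0.5,
    seed: int = 0,
) -> SimulationConfig:
    """One site, three replicate cores, six horizons, convergent selection.

    The selection pull decays within about one horizon (tau = 0.5): sediment
    layers are geochemically distinct zones, so a clade's optimum is confined
    to a narrow depth band. A slower decay would pull every site's frequency
    to an intermediate value across several horizons, saturating the
    shared-SNV fraction at 1 there and leaving its maximum undefined.
    """
    mag = MagSpec(
        mag_id="MAG_sim",
        genome_length_bp=2 * n_sites,
        n_variable_sites=n_sites,
        f_realm=0.0,
        f_trench=0.0,
        f_site=0.0,
        f_core=f_core,
        selection_strength=s,
        optimal_horizon=optimal_rank,
        tau=tau,
        coverage_peak=coverage_peak,
        coverage_floor=coverage_floor,
        error_rate=0.005,
    )
    sites = [SiteSpec("A7", "Atacama", "abyssal", 5500.0, n_cores=3)]
    return SimulationConfig(seed=seed, sites=sites, mags=[mag])


def niche_signature(
    n_replicates: int = 20,
    s: float = 0.6,
    optimal_rank: int = 2,
    seed: int = 0,
) -> dict:
    """Downcore niche-selection signature across seeded replicates.

    For each replicate the full pipeline path runs (simulate -> SNVs -> F_ST
    matrix -> pair classification -> shared-SNV statistics). Returns per-
    replicate indicators of whether the horizon of minimum mean inter-core
    F_ST, maximum shared-SNV fraction and maximum same-consensus fraction is
    the configured optimal horizon, plus pooled regression slopes of F_ST on
    the shared-variant fractions and Kruskal-Wallis p-values for the
    inter- vs intra-core contrast.
    """
    seeds = _child_seeds(seed, n_replicates)
    result = {
        "fst_argmin_hits": 0,
        "shared_argmax_hits": 0,
        "consensus_argmax_hits": 0,
        "all_three_hits": 0,
        "kruskal_p": [],
        "pooled_points": [],
    }
    optimal_label = None
    for sub_seed in seeds:
        config = niche_config(s=s, optimal_rank=optimal_rank, seed=int(sub_seed))
        optimal_label = config.sites[0].horizons[optimal_rank].label
        truth, counts, _ = simulate_bundle(config)
        snvs = call_snvs(counts, min_coverage=10, min_departure=0.1)
        sample_ids = sorted(counts["sample_id"].unique())
        matrix = fst_matrix(counts, snvs, sample_ids, min_coverage=10)
        pairs = build_pair_comparisons(counts, snvs, matrix, truth.samples, min_coverage=10)
        summary = horizon_summary(pairs)
        fst_hit = summary.loc[summary["fst"].idxmin(), "horizon"] == optimal_label
        shared_hit = summary.loc[summary["pct_shared"].idxmax(), "horizon"] == optimal_label
        cons_hit = (
            summary.loc[summary["pct_same_consensus"].idxmax(), "horizon"] == optimal_label
        )
        result["fst_argmin_hits"] += int(fst_hit)
        result["shared_argmax_hits"] += int(shared_hit)
        result["consensus_argmax_hits"] += int(cons_hit)
        result["all_three_hits"] += int(fst_hit and shared_hit and cons_hit)
        _, kw_p, _ = intercore_vs_intracore_test(pairs)
        result["kruskal_p"].append(kw_p)
        inter = pairs[pairs["kind"] == "inter_core"]
        result["pooled_points"].append(
            inter[["fst", "pct_shared", "pct_same_consensus"]].to_numpy()
        )
    pooled = np.vstack(result.pop("pooled_points"))
    from .shared import ols_fit

    result["slope_fst_vs_shared"] = ols_fit(pooled[:, 1], pooled[:, 0]).slope
    result["slope_fst_vs_consensus"] = ols_fit(pooled[:, 2], pooled[:, 0]).slope
    result["n_replicates"] = n_replicates
    result["optimal_horizon"] = optimal_label
    return result
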