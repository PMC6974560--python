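"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study design the pipeline expects:

* batch-culture growth assays read as OD600 plus headspace CO2 (three-phase
  biomass: flat lag, exact exponential, logistic-style saturation; CO2
  accumulates in proportion to integrated biomass at the mass-specific
  respiration rate implied by the target CUE);
* ultrametric Yule / birth-death phylogenies;
* tip traits evolving under lambda-transformed Brownian motion;
* genome feature (KO count) tables with phylogenetically autocorrelated
  densities, prevalence structure, and optional planted causal effects on
  CUE;
* community (KO relative abundance, CUE) tables for microcosm-style marker
  validation;
* coding sequences with tunable codon bias and their protein translations.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import dataclasses
import random as _pyrandom
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

from .phylocomp import vcv_matrix, lambda_transform

__all__ = [
    "GrowthSimParams",
    "TreeSimParams",
    "TraitSimParams",
    "GenomeSimParams",
    "simulate_growth_experiment",
    "simulate_tree",
    "simulate_trait_bm",
    "simulate_genomes",
    "simulate_communities",
    "simulate_cds",
    "CODON_TABLE",
    "write_fasta",
]

ATM_PA = 101325.0
GAS_R = 8.314462618  # J / (mol K)
CARBON_UG_PER_UMOL = 12.011
BASELINE_PPM = 420.0


# ---------------------------------------------------------------------------
# Growth assays

@dataclasses.dataclass
class GrowthSimParams:
    """Ground truth and assay geometry for one simulated growth condition.

    ``mu_true`` (h^-1) and ``cue_true`` (dimensionless, in (0, 1]) define the
    mass-specific respiration rate R = mu * (1 - CUE) / CUE.  OD noise is
    multiplicative log-normal (read error grows with signal); CO2 noise is
    additive Gaussian in ppm.
    """

    mu_true: float = 0.3
    cue_true: float = 0.6
    od_start: float = 0.02
    od_max: float = 0.8
    lag_h: float = 2.0
    duration_h: float = 24.0
    read_interval_h: float = 1.0
    od_noise_sd: float = 0.01
    co2_noise_sd: float = 5.0
    headspace_ml: float = 25.0
    culture_ml: float = 10.0
    temperature_c: float = 25.0
    biomass_per_od: float = 130.0  # ug C per OD unit per ml culture
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cue_true <= 1.0):
            raise ValueError("cue_true must lie in (0, 1]")
        if self.mu_true <= 0:
            raise ValueError("mu_true must be positive")
        if not self.od_start < self.od_max:
            raise ValueError("od_start must be below od_max")
        if self.read_interval_h <= 0:
            raise ValueError("read_interval_h must be positive")
        for name in ("od_start", "lag_h", "duration_h", "od_noise_sd",
                     "co2_noise_sd", "headspace_ml", "culture_ml",
                     "biomass_per_od"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.headspace_ml <= 0 or self.culture_ml <= 0:
            raise ValueError("volumes must be positive")

    @property
    def r_true(self) -> float:
        """Mass-specific respiration rate implied by mu and CUE (h^-1)."""
        return self.mu_true * (1.0 - self.cue_true) / self.cue_true


def _od_deterministic(t: np.ndarray, p: GrowthSimParams) -> np.ndarray:
    """Three-phase biomass curve: flat lag, exact exponential, saturation.

    The exponential phase runs at exactly ``mu_true`` until OD reaches half
    of ``od_max``; after that the curve relaxes exponentially toward
    ``od_max`` with matched slope (C1-continuous logistic-style approach).
    """
    mu = p.mu_true
    od_switch = 0.5 * p.od_max
    t_switch = p.lag_h + np.log(od_switch / p.od_start) / mu
    od = np.empty_like(t, dtype=float)
    lagm = t <= p.lag_h
    expm = (t > p.lag_h) & (t <= t_switch)
    satm = t > t_switch
    od[lagm] = p.od_start
    od[expm] = p.od_start * np.exp(mu * (t[expm] - p.lag_h))
    od[satm] = p.od_max - (p.od_max - od_switch) * np.exp(-mu * (t[satm] - t_switch))
    return od


def _cum_co2_c(t: np.ndarray, p: GrowthSimParams) -> np.ndarray:
    """Cumulative respired CO2 carbon (ug) = R * integral of biomass C dt.

    Closed-form piecewise integral of the three-phase biomass curve, so a
    noiseless simulation is exact (no quadrature error) and downstream
    estimators can be validated to numerical precision.
    """
    mu, r = p.mu_true, p.r_true
    b0 = p.od_start * p.biomass_per_od * p.culture_ml  # ug C
    bmax = p.od_max * p.biomass_per_od * p.culture_ml
    bs = 0.5 * bmax
    t_switch = p.lag_h + np.log(bs / b0) / mu
    out = np.empty_like(t, dtype=float)
    lag_int = b0 * np.minimum(t, p.lag_h)
    out[:] = lag_int
    expm = (t > p.lag_h) & (t <= t_switch)
    te = t[expm] - p.lag_h
    out[expm] += (b0 / mu) * (np.exp(mu * te) - 1.0)
    satm = t > t_switch
    exp_int_full = (b0 / mu) * (np.exp(mu * (t_switch - p.lag_h)) - 1.0)
    ts = t[satm] - t_switch
    out[satm] += exp_int_full + bmax * ts + ((bmax - bs) / mu) * (np.exp(-mu * ts) - 1.0)
    return r * out


def _headspace_total_umol(headspace_ml: float, temperature_c: float) -> float:
    """Total gas in the headspace (umol) at 1 atm by the ideal-gas law."""
    t_k = temperature_c + 273.15
    mol = ATM_PA * (headspace_ml * 1e-6) / (GAS_R * t_k)
    return mol * 1e6


def simulate_growth_experiment(
    params: GrowthSimParams,
    n_replicates: int,
    isolate: str = "iso1",
    substrate: str = "glucose",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate replicate growth curves for one isolate x substrate x T.

    Returns
    -------
    curves : tidy frame (isolate, substrate, temperature_c, replicate,
        time_h, od600, co2_ppm), one row per read.
    truth : one row per replicate with the generating mu_true, r_true,
        cue_true and assay geometry (the ground-truth sidecar).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    t = np.arange(0.0, params.duration_h + 1e-9, params.read_interval_h)
    od_det = _od_deterministic(t, params)
    cum_c = _cum_co2_c(t, params)
    total_umol = _headspace_total_umol(params.headspace_ml, params.temperature_c)
    ppm_det = BASELINE_PPM + (cum_c / CARBON_UG_PER_UMOL) / total_umol * 1e6
    rng = np.random.default_rng(params.seed)
    frames = []
    truth_rows = []
    for rep in range(1, n_replicates + 1):
        od = od_det * np.exp(rng.normal(0.0, params.od_noise_sd, size=t.shape)) \
            if params.od_noise_sd > 0 else od_det.copy()
        ppm = ppm_det + rng.normal(0.0, params.co2_noise_sd, size=t.shape) \
            if params.co2_noise_sd > 0 else ppm_det.copy()
        frames.append(
            pd.DataFrame(
                {
                    "isolate": isolate,
                    "substrate": substrate,
                    "temperature_c": params.temperature_c,
                    "replicate": f"r{rep}",
                    "time_h": t,
                    "od600": od,
                    "co2_ppm": ppm,
                }
            )
        )
        truth_rows.append(
            {
                "isolate": isolate,
                "substrate": substrate,
                "temperature_c": params.temperature_c,
                "replicate": f"r{rep}",
                "mu_true": params.mu_true,
                "r_true": params.r_true,
                "cue_true": params.cue_true,
                "biomass_per_od": params.biomass_per_od,
                "culture_ml": params.culture_ml,
                "headspace_ml": params.headspace_ml,
            }
        )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Trees

@dataclasses.dataclass
class TreeSimParams:
    """Yule or birth-death tree simulation settings."""

    n_tips: int = 16
    model: str = "yule"
    birth_rate: float = 1.0
    death_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.model not in ("yule", "birth-death"):
            raise ValueError("model must be 'yule' or 'birth-death'")
        if self.model == "yule" and self.death_rate != 0.0:
            raise ValueError("yule model has death_rate 0")
        if self.death_rate >= self.birth_rate:
            raise ValueError("death_rate must be below birth_rate")


def simulate_tree(params: TreeSimParams) -> dendropy.Tree:
    """Simulate an ultrametric rooted binary tree with labelled tips t1..tn.

    The constant-rate birth-death process is stopped at ``n_tips`` extant
    lineages; terminal branches are then extended by an exponential draw of
    the waiting time to the next event so that the final speciation does not
    leave zero-length terminals.
    """
    from dendropy.model import birthdeath

    rng = _pyrandom.Random(params.seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=params.birth_rate,
        death_rate=params.death_rate,
        num_extant_tips=params.n_tips,
        rng=rng,
    )
    extra = rng.expovariate(
        params.n_tips * (params.birth_rate + params.death_rate)
    )
    leaves = sorted(
        tree.leaf_node_iter(), key=lambda lf: lf.taxon.label if lf.taxon else ""
    )
    ns = dendropy.TaxonNamespace()
    for i, leaf in enumerate(leaves, start=1):
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
        leaf.taxon = ns.new_taxon(label=f"t{i}")
    tree.taxon_namespace = ns
    tree.seed_node.edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# Traits

@dataclasses.dataclass
class TraitSimParams:
    """Lambda-transformed Brownian motion trait simulation settings."""

    sigma2: float = 1.0
    lambda_sim: float = 1.0
    root_value: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if not 0.0 <= self.lambda_sim <= 1.0:
            raise ValueError("lambda_sim must lie in [0, 1]")


def simulate_trait_bm(tree: dendropy.Tree, params: TraitSimParams) -> pd.Series:
    """One draw of a tip trait with covariance sigma2 * V_lambda.

    V is the shared-branch-length matrix of the tree; lambda_sim scales its
    off-diagonal entries (1 = plain BM, 0 = phylogenetically independent
    tips with BM-sized variances).
    """
    V, labels = vcv_matrix(tree)
    if len(labels) < 3:
        raise ValueError("tree must have >= 3 tips")
    rng = np.random.default_rng(params.seed)
    if params.sigma2 == 0.0:
        return pd.Series(np.full(len(labels), params.root_value), index=labels)
    Vl = lambda_transform(V, params.lambda_sim)
    L = linalg.cholesky(Vl, lower=True)
    y = params.root_value + np.sqrt(params.sigma2) * (L @ rng.standard_normal(len(labels)))
    return pd.Series(y, index=labels)


# ---------------------------------------------------------------------------
# Genome feature tables with planted markers

@dataclasses.dataclass
class GenomeSimParams:
    """Settings for KO-count tables with planted CUE effects.

    KO log-densities evolve by BM on the tree (phylogenetic autocorrelation)
    around KO-specific baselines and are zero-truncated to a KO-specific
    prevalence target, producing the rare-function gradient the prevalence
    filter needs.  CUE is a linear function of the causal KO densities plus
    BM noise, clipped to (0, 1).
    """

    n_kos: int = 200
    n_causal: int = 5
    effect_size: float = 0.1  # CUE units per (count / Mbp)
    density_dispersion: float = 0.25  # BM rate of log density across the tree
    genome_size_range: tuple[float, float] = (2.0, 8.0)  # Mbp
    prevalence_range: tuple[float, float] = (0.4, 1.0)
    cue_base: float = 0.55
    cue_noise_sigma2: float = 0.002  # BM rate of the CUE residual
    causal_correlation: float = 0.7  # shared-factor variance among causal KOs
    causal_prevalence: float | None = None  # fix causal KO prevalence (else drawn)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_kos:
            raise ValueError("n_causal cannot exceed n_kos")
        if self.n_causal < 0 or self.n_kos < 1:
            raise ValueError("counts must be non-negative")
        if self.genome_size_range[0] <= 0:
            raise ValueError("genome sizes must be positive")


def simulate_genomes(
    tree: dendropy.Tree, params: GenomeSimParams
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Simulate a taxa x KO count table, CUE, and the planted causal KO ids.

    Returns
    -------
    features : DataFrame indexed by taxon with KO count columns plus a
        ``genome_size`` column (Mbp).
    cue : Series of CUE values per taxon.
    causal_ids : KO ids whose density truly affects CUE (empty when
        ``n_causal == 0``).
    """
    V, labels = vcv_matrix(tree)
    n = len(labels)
    rng = np.random.default_rng(params.seed)
    L = linalg.cholesky(V, lower=True)
    ko_ids = [f"K{j:05d}" for j in range(1, params.n_kos + 1)]
    # Phylogenetically autocorrelated log densities (counts per Mbp).
    base = rng.normal(0.7, 0.4, size=params.n_kos)
    Z = L @ rng.standard_normal((n, params.n_kos))
    causal_pos = rng.choice(params.n_kos, size=params.n_causal, replace=False)
    if params.n_causal > 1 and params.causal_correlation > 0:
        # Causal KOs co-vary like members of one pathway: a shared BM factor
        # carries `causal_correlation` of their log-density variance.
        rho = params.causal_correlation
        shared = L @ rng.standard_normal(n)
        Z[:, causal_pos] = (
            np.sqrt(rho) * shared[:, None]
            + np.sqrt(1.0 - rho) * Z[:, causal_pos]
        )
    logdens = base[None, :] + np.sqrt(params.density_dispersion) * Z
    dens = np.exp(logdens)
    # Zero-truncate to a per-KO prevalence target.  Causal KOs may be pinned
    # to a fixed (typically high) prevalence: a marker generalising across
    # data sets is necessarily a widespread function.
    prev = rng.uniform(*params.prevalence_range, size=params.n_kos)
    if params.causal_prevalence is not None:
        prev[causal_pos] = params.causal_prevalence
    for j in range(params.n_kos):
        if prev[j] < 1.0:
            thresh = np.quantile(dens[:, j], 1.0 - prev[j])
            dens[dens[:, j] < thresh, j] = 0.0
    genome_size = rng.uniform(*params.genome_size_range, size=n)
    counts = np.rint(dens * genome_size[:, None]).astype(int)
    dens_real = counts / genome_size[:, None]
    causal_idx = sorted(int(j) for j in causal_pos)
    causal = [ko_ids[j] for j in causal_idx]
    noise = np.sqrt(params.cue_noise_sigma2) * (L @ rng.standard_normal(n))
    cue = params.cue_base + noise
    if causal_idx:
        centred = dens_real[:, causal_idx] - dens_real[:, causal_idx].mean(axis=0)
        cue = cue + params.effect_size * centred.sum(axis=1)
    cue = np.clip(cue, 1e-3, 1.0 - 1e-3)
    features = pd.DataFrame(counts, index=labels, columns=ko_ids)
    features["genome_size"] = genome_size
    return features, pd.Series(cue, index=labels, name="cue"), causal


def simulate_substrate_cues(
    tree: dendropy.Tree,
    features: pd.DataFrame,
    causal_ids: Sequence[str],
    params: GenomeSimParams,
    substrates: Sequence[str],
    seed: int = 0,
) -> dict[str, pd.Series]:
    """CUE on additional substrates sharing the planted causal effects.

    Each substrate's CUE uses the same causal KO densities and effect size
    as the glucose table from :func:`simulate_genomes` but an independent
    BM noise draw — markers truly shared across substrates can then be
    validated by the explore/validate pipeline.
    """
    V, labels = vcv_matrix(tree)
    L = linalg.cholesky(V, lower=True)
    genome_size = features["genome_size"].reindex(labels)
    dens = features.drop(columns="genome_size").reindex(labels).div(genome_size, axis=0)
    rng = np.random.default_rng(seed)
    out: dict[str, pd.Series] = {}
    causal = list(causal_ids)
    for sub in substrates:
        noise = np.sqrt(params.cue_noise_sigma2) * (L @ rng.standard_normal(len(labels)))
        cue = params.cue_base + noise
        if causal:
            centred = dens[causal] - dens[causal].mean(axis=0)
            cue = cue + params.effect_size * centred.sum(axis=1).to_numpy()
        out[sub] = pd.Series(
            np.clip(cue, 1e-3, 1.0 - 1e-3), index=labels, name=f"cue_{sub}"
        )
    return out


def simulate_communities(
    n_communities: int,
    ko_ids: Sequence[str],
    causal_ids: Sequence[str],
    effect_size: float = 0.5,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate microcosm validation data: KO relative abundance vs CUE.

    Each community draws a latent CUE; causal KO relative abundances track
    it linearly (slope ``effect_size`` on the relative-abundance scale)
    with Gaussian noise, other KOs are independent of CUE.  Returns a frame
    with one row per community, KO columns, and a ``cue`` column.
    """
    if n_communities < 5:
        raise ValueError("need >= 5 communities")
    rng = np.random.default_rng(seed)
    cue = rng.uniform(0.2, 0.8, size=n_communities)
    raw = rng.lognormal(0.0, 0.5, size=(n_communities, len(ko_ids)))
    cols = {k: i for i, k in enumerate(ko_ids)}
    for k in causal_ids:
        j = cols[k]
        raw[:, j] = np.exp(
            effect_size * (cue - cue.mean()) / cue.std()
            + rng.normal(0.0, noise_sd, size=n_communities)
        )
    rel = raw / raw.sum(axis=1, keepdims=True)
    out = pd.DataFrame(rel, columns=list(ko_ids),
                       index=[f"c{i+1}" for i in range(n_communities)])
    out["cue"] = cue
    return out


# ---------------------------------------------------------------------------
# Coding sequences with controlled codon bias

# Standard genetic code, stop codons excluded (no internal stops are emitted).
CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}

_SYNONYMOUS: dict[str, list[str]] = {}
for codon, aa in CODON_TABLE.items():
    _SYNONYMOUS.setdefault(aa, []).append(codon)
for fam in _SYNONYMOUS.values():
    fam.sort()

AMINO_ACIDS = sorted(_SYNONYMOUS)


def default_reference_codon_freqs(seed: int = 12345) -> dict[str, float]:
    """A fixed, skewed reference codon usage (per-family frequencies sum to 1).

    Emulates the strong bias of highly expressed genes: within each
    synonymous family the frequencies fall off geometrically (ratio 0.35)
    from a randomly chosen preferred codon.
    """
    rng = np.random.default_rng(seed)
    freqs: dict[str, float] = {}
    for aa, fam in _SYNONYMOUS.items():
        order = rng.permutation(len(fam))
        weights = 0.35 ** np.arange(len(fam), dtype=float)
        weights = weights / weights.sum()
        for rank, idx in enumerate(order):
            freqs[fam[idx]] = float(weights[rank])
    return freqs


def simulate_cds(
    n_genes: int,
    codon_bias_strength: float,
    reference_codon_freqs: dict[str, float] | None = None,
    seed: int = 0,
    mean_length_aa: int = 250,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Simulate coding sequences with tunable codon bias.

    Codon choice per residue interpolates between uniform synonymous usage
    (strength 0) and always the reference-preferred codon (strength 1):
    p(codon) = (1 - s)/k + s * [codon is preferred].

    Returns ``(cds_records, protein_records)`` as (id, sequence) pairs;
    proteins are the exact translations of the emitted CDS.
    """
    if not 0.0 <= codon_bias_strength <= 1.0:
        raise ValueError("codon_bias_strength must lie in [0, 1]")
    if reference_codon_freqs is None:
        reference_codon_freqs = default_reference_codon_freqs()
    for aa, fam in _SYNONYMOUS.items():
        tot = sum(reference_codon_freqs.get(c, 0.0) for c in fam)
        if not np.isclose(tot, 1.0, atol=1e-6):
            raise ValueError(f"reference frequencies for {aa} must sum to 1")
    rng = np.random.default_rng(seed)
    s = codon_bias_strength
    preferred = {
        aa: max(fam, key=lambda c: reference_codon_freqs[c])
        for aa, fam in _SYNONYMOUS.items()
    }
    cds_records, protein_records = [], []
    aas = [a for a in AMINO_ACIDS if a != "M"]
    for g in range(1, n_genes + 1):
        length = max(30, int(rng.poisson(mean_length_aa)))
        protein = "M" + "".join(rng.choice(aas, size=length - 1))
        codons = []
        for aa in protein:
            fam = _SYNONYMOUS[aa]
            probs = np.full(len(fam), (1.0 - s) / len(fam))
            probs[fam.index(preferred[aa])] += s
            codons.append(fam[rng.choice(len(fam), p=probs)])
        gid = f"gene{g:04d}"
        cds_records.append((gid, "".join(codons)))
        protein_records.append((gid, protein))
    return cds_records, protein_records


def write_fasta(records: Sequence[tuple[str, str]], path: str) -> None:
    """Write (id, sequence) pairs as FASTA with 70-column wrapping."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
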