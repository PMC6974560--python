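"""Explore/validate discovery of genomic markers of CUE.

The design guards against false discovery by conjunction rather than by
multiple-testing correction: a feature becomes a *final* marker only when

1. its PGLS slope against CUE is significant (raw alpha) in an exploration
   subset of taxa grown on glucose,
2. the full glucose data set shows a significant slope in the same
   direction,
3. at least one independent validation route agrees — the same-direction
   significant slope in >= 2 of 3 other substrates, or a same-sign
   significant Spearman correlation in community (microcosm) data, and
4. the full-glucose model's residuals retain no phylogenetic signal.

Rare features (present in fewer than ``min_prevalence`` genomes) are
removed before testing; feature counts are standardised to densities per
Mbp of genome.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import phylocomp

__all__ = [
    "standardize_density",
    "prevalence_filter",
    "explore_markers",
    "validate_other_substrates",
    "validate_microcosm",
    "finalize_markers",
    "test_a_priori_hypotheses",
    "ValidationReport",
]


def standardize_density(
    counts: pd.DataFrame, genome_size_mbp: pd.Series | None = None
) -> pd.DataFrame:
    """Genome-size-standardised feature densities (counts per Mbp).

    ``counts`` may carry a ``genome_size`` column (as written by the
    simulator) or sizes may be passed separately.
    """
    counts = counts.copy()
    if genome_size_mbp is None:
        if "genome_size" not in counts.columns:
            raise ValueError("genome_size column or series required")
        genome_size_mbp = counts.pop("genome_size")
    genome_size_mbp = genome_size_mbp.reindex(counts.index)
    if (genome_size_mbp <= 0).any():
        raise ValueError("genome sizes must be positive")
    return counts.div(genome_size_mbp, axis=0)


def prevalence_filter(table: pd.DataFrame, min_prevalence: int = 4) -> pd.DataFrame:
    """Keep features with a nonzero value in at least ``min_prevalence`` taxa."""
    if min_prevalence < 1:
        raise ValueError("min_prevalence must be >= 1")
    keep = (table != 0).sum(axis=0) >= min_prevalence
    return table.loc[:, keep]


def _scan_lambda_grid(Vsub, cue, taxa, lambda_mode: str):
    """Lambda grid for mass screens: the response's ML lambda, or a profile
    grid when per-feature re-estimation is requested."""
    if lambda_mode == "profile":
        return None
    if lambda_mode != "response":
        raise ValueError("lambda_mode must be 'response' or 'profile'")
    lam = phylocomp.pagel_lambda_ml(Vsub, cue, labels=taxa).lambda_hat
    return np.array([lam])


def explore_markers(
    tree,
    cue_glucose: pd.Series,
    features: pd.DataFrame,
    explore_taxa: Sequence[str],
    alpha: float = 0.05,
    min_prevalence: int = 4,
    lambda_mode: str = "response",
) -> pd.DataFrame:
    """Exploration pass: per-feature PGLS of CUE on density in a taxon subset.

    ``lambda_mode='response'`` (default) fixes the error-covariance lambda
    at the ML value of the CUE vector itself, which keeps the mass screen's
    type-I rate at alpha; ``'profile'`` re-estimates lambda per feature
    (slightly anticonservative across thousands of features).

    Returns one row per retained feature with slope, p, lambda and a
    ``candidate`` flag (p <= alpha); the slope sign is the direction later
    validation stages must reproduce.
    """
    explore_taxa = list(explore_taxa)
    if len(explore_taxa) < 6:
        raise ValueError("PGLS screening needs >= 6 exploration taxa")
    missing = [t for t in explore_taxa if t not in cue_glucose.index]
    if missing:
        raise ValueError(f"exploration taxa without CUE values: {missing[:5]}")
    dens = prevalence_filter(features.loc[explore_taxa], min_prevalence)
    V, labels = phylocomp.vcv_matrix(tree)
    idx = [labels.index(t) for t in explore_taxa]
    Vsub = V[np.ix_(idx, idx)]
    scan = phylocomp.pgls_scan(
        Vsub, cue_glucose.loc[explore_taxa], dens, labels=explore_taxa,
        lambda_grid=_scan_lambda_grid(Vsub, cue_glucose.loc[explore_taxa],
                                      explore_taxa, lambda_mode),
    )
    scan = scan.rename(columns={"p": "p_explore", "slope": "slope_explore"})
    scan["direction"] = np.sign(scan["slope_explore"])
    scan["prevalence"] = (features.loc[explore_taxa, scan.index] != 0).sum(axis=0)
    scan["candidate"] = scan["p_explore"] <= alpha
    return scan


def validate_other_substrates(
    candidates: pd.DataFrame,
    cue_by_substrate: Mapping[str, pd.Series],
    tree,
    features: pd.DataFrame,
    alpha: float = 0.05,
    min_substrates: int = 2,
    lambda_mode: str = "response",
) -> pd.DataFrame:
    """Substrate validation: same-direction significant slope in >= 2 of 3
    other substrates.

    Substrates with no CUE data are skipped without changing the required
    count.  Adds per-substrate slope/p columns and a
    ``validated_other_substrates`` flag to the candidate table.
    """
    out = candidates.copy()
    hits = pd.Series(0, index=out.index)
    V, labels = phylocomp.vcv_matrix(tree)
    for sub, cue in cue_by_substrate.items():
        cue = cue.dropna()
        taxa = [t for t in labels if t in cue.index]
        if len(taxa) < 6:
            continue
        idx = [labels.index(t) for t in taxa]
        Vsub = V[np.ix_(idx, idx)]
        scan = phylocomp.pgls_scan(
            Vsub, cue.loc[taxa],
            features.loc[taxa, out.index], labels=taxa,
            lambda_grid=_scan_lambda_grid(Vsub, cue.loc[taxa], taxa, lambda_mode),
        )
        out[f"slope_{sub}"] = scan["slope"]
        out[f"p_{sub}"] = scan["p"]
        same_dir = np.sign(scan["slope"]) == out["direction"]
        hits += ((scan["p"] <= alpha) & same_dir).astype(int)
    out["n_substrates_validated"] = hits
    out["validated_other_substrates"] = hits >= min_substrates
    return out


def validate_microcosm(
    candidates: pd.DataFrame,
    community_table: pd.DataFrame,
    alpha: float = 0.05,
    cue_column: str = "cue",
) -> pd.DataFrame:
    """Community validation: Spearman correlation of KO relative abundance
    with community CUE, passing on p <= alpha with the exploration sign.

    Features constant across communities have undefined rho and fail with
    reason recorded as NaN statistics.
    """
    if len(community_table) < 5:
        raise ValueError("need >= 5 communities")
    out = candidates.copy()
    cue = community_table[cue_column]
    rhos, ps = [], []
    for feat in out.index:
        if feat not in community_table.columns:
            rhos.append(np.nan)
            ps.append(np.nan)
            continue
        x = community_table[feat]
        if np.allclose(x, x.iloc[0]):
            rhos.append(np.nan)
            ps.append(np.nan)
            continue
        rho, p = sps.spearmanr(x, cue)
        rhos.append(float(rho))
        ps.append(float(p))
    out["microcosm_rho"] = rhos
    out["microcosm_p"] = ps
    same_dir = np.sign(out["microcosm_rho"]) == out["direction"]
    out["validated_microcosm"] = (
        (out["microcosm_p"] <= alpha) & same_dir & out["microcosm_rho"].notna()
    )
    return out


@dataclasses.dataclass
class ValidationReport:
    """Venn-style tallies of candidate markers across validation routes."""

    n_explore: int
    n_full_glucose: int
    n_other_substrates: int
    n_microcosm: int
    n_final: int
    n_positive_final: int
    n_negative_final: int
    overlap: pd.DataFrame  # membership booleans per candidate

    def region_counts(self) -> pd.Series:
        """Counts per Venn region over the three validation memberships."""
        cols = ["full_glucose", "other_substrates", "microcosm"]
        return self.overlap.groupby(cols).size()


def finalize_markers(
    candidates: pd.DataFrame,
    tree,
    cue_full_glucose: pd.Series,
    features: pd.DataFrame,
    alpha: float = 0.05,
    residual_seed: int | None = 0,
    n_perm: int = 199,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Final-marker call: full-glucose confirmation plus residual diagnostics.

    Each exploration candidate is refit by PGLS on the full glucose data
    set; a marker is final when that fit is significant in the exploration
    direction, at least one validation route passed, and the full-glucose
    residuals carry no phylogenetic signal.
    """
    out = candidates.copy()
    cand_idx = out.index[out["candidate"]]
    V, labels = phylocomp.vcv_matrix(tree)
    taxa = [t for t in labels if t in cue_full_glucose.dropna().index]
    idx = [labels.index(t) for t in taxa]
    Vsub = V[np.ix_(idx, idx)]
    full_p = pd.Series(np.nan, index=out.index)
    full_slope = pd.Series(np.nan, index=out.index)
    resid_pass = pd.Series(False, index=out.index)
    for feat in cand_idx:
        fit = phylocomp.pgls_fit(
            Vsub, cue_full_glucose.loc[taxa], features.loc[taxa, feat],
            labels=taxa,
        )
        full_slope[feat] = fit.params.iloc[1]
        full_p[feat] = fit.pvalues.iloc[1]
        chk = phylocomp.residual_phylosig_check(
            fit, Vsub, alpha=alpha, n_perm=n_perm, seed=residual_seed
        )
        resid_pass[feat] = bool(chk["passed"])
    out["slope_full_glucose"] = full_slope
    out["p_full_glucose"] = full_p
    out["residual_check_pass"] = resid_pass
    full_ok = (
        (full_p <= alpha) & (np.sign(full_slope) == out["direction"])
    ).fillna(False)
    out["validated_full_glucose"] = full_ok
    for col in ("validated_other_substrates", "validated_microcosm"):
        if col not in out.columns:
            out[col] = False
    out["final"] = (
        out["candidate"]
        & full_ok
        & (out["validated_other_substrates"] | out["validated_microcosm"])
        & resid_pass
    )
    final = out[out["final"]]
    overlap = pd.DataFrame(
        {
            "full_glucose": out.loc[cand_idx, "validated_full_glucose"],
            "other_substrates": out.loc[cand_idx, "validated_other_substrates"],
            "microcosm": out.loc[cand_idx, "validated_microcosm"],
        }
    )
    report = ValidationReport(
        n_explore=int(out["candidate"].sum()),
        n_full_glucose=int(full_ok.sum()),
        n_other_substrates=int(out["validated_other_substrates"].sum()),
        n_microcosm=int(out["validated_microcosm"].sum()),
        n_final=len(final),
        n_positive_final=int((final["direction"] > 0).sum()),
        n_negative_final=int((final["direction"] < 0).sum()),
        overlap=overlap,
    )
    return out, report


#: Default a-priori hypothesis pairs: response column -> predictor column.
DEFAULT_HYPOTHESES: list[tuple[str, str]] = [
    ("cue", "max_growth_rate"),
    ("cue", "rrN"),
    ("cue", "log2_rrN"),
    ("cue", "pathway_count"),
    ("cue", "exoenzyme_cue"),
    ("max_growth_rate", "rrN"),
    ("q10", "pathway_count"),
    ("q10", "ee_density"),
    ("q10", "transporter_density"),
]


def test_a_priori_hypotheses(
    tree,
    traits: pd.DataFrame,
    hypotheses: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """PGLS slope per literature-motivated (response, predictor) pair.

    ``traits`` holds one column per variable, indexed by taxon; hypotheses
    whose columns are missing or degenerate are reported with a reason and
    the rest still run.  ``log2_<col>`` predictors are derived on the fly.
    """
    if hypotheses is None:
        hypotheses = [
            (r, p) for r, p in DEFAULT_HYPOTHESES
            if r in traits.columns
            and (p in traits.columns or (p.startswith("log2_") and p[5:] in traits.columns))
        ]
    V, labels = phylocomp.vcv_matrix(tree)
    rows = []
    for resp, pred in hypotheses:
        row = {"response": resp, "predictor": pred, "slope": np.nan, "se": np.nan,
               "t": np.nan, "p": np.nan, "lambda": np.nan, "n": 0, "note": ""}
        if resp not in traits.columns:
            row["note"] = "response column missing"
            rows.append(row)
            continue
        if pred.startswith("log2_") and pred not in traits.columns:
            base = pred[5:]
            if base not in traits.columns:
                row["note"] = "predictor column missing"
                rows.append(row)
                continue
            x = np.log2(traits[base].astype(float))
        elif pred in traits.columns:
            x = traits[pred].astype(float)
        else:
            row["note"] = "predictor column missing"
            rows.append(row)
            continue
        data = pd.DataFrame({"y": traits[resp].astype(float), "x": x}).dropna()
        taxa = [t for t in labels if t in data.index]
        if len(taxa) < 6:
            row["note"] = "fewer than 6 complete taxa"
            rows.append(row)
            continue
        if np.allclose(data.loc[taxa, "x"], data.loc[taxa, "x"].iloc[0]):
            row["note"] = "constant predictor, fit skipped"
            rows.append(row)
            continue
        idx = [labels.index(t) for t in taxa]
        fit = phylocomp.pgls_fit(
            V[np.ix_(idx, idx)], data.loc[taxa, "y"], data.loc[taxa, ["x"]],
            labels=taxa,
        )
        row.update(
            slope=float(fit.params.iloc[1]), se=float(fit.bse.iloc[1]),
            t=float(fit.tvalues.iloc[1]), p=float(fit.pvalues.iloc[1]),
            **{"lambda": float(fit.residual_lambda)}, n=fit.n,
        )
        rows.append(row)
    return pd.DataFrame(rows)
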