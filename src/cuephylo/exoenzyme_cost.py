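"""Theoretical carbon cost of extracellular enzyme production.

Secreted enzymes are pure carbon expenditure until their products return:
each residue costs ATP to synthesise de novo plus 4.2 ATP per peptide bond
to polymerise, and regenerating that ATP respires glucose carbon at 26 ATP
per 6 glucose C.  The per-protein carbon assimilation efficiency is

    CUE_protein = C_protein / (C_protein + C_respired),
    C_respired  = ATP_total * 6 / 26.

An organism-level value weights each exoenzyme's CUE by its predicted
relative expression, inferred from codon usage bias (CAI against a
highly-expressed reference gene set, normalised to sum to 1 over the
exoenzyme set).

Amino-acid ATP costs are an input table (residue, atp_cost, n_carbon); a
synthetic example ships with the package.
"""

from __future__ import annotations

import dataclasses
import fnmatch
import math
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .synthetic_data import CODON_TABLE, _SYNONYMOUS

__all__ = [
    "CostParameters",
    "load_cost_table",
    "residue_carbons",
    "protein_atp_cost",
    "protein_cue",
    "codon_bias_weights",
    "organism_exoenzyme_cue",
    "keyword_filter",
    "EnzymeCostResult",
    "CodonBiasModel",
    "RESIDUE_CARBONS",
]

#: Carbon atoms per residue as incorporated in a peptide (standard chemistry).
RESIDUE_CARBONS: dict[str, int] = {
    "A": 3, "R": 6, "N": 4, "D": 4, "C": 3, "E": 5, "Q": 5, "G": 2, "H": 6,
    "I": 6, "L": 6, "K": 6, "M": 5, "F": 9, "P": 5, "S": 3, "T": 4, "W": 11,
    "Y": 9, "V": 5,
}

_STOPS = {"TAA", "TAG", "TGA"}


@dataclasses.dataclass
class CostParameters:
    """ATP stoichiometry of protein production and glucose catabolism."""

    atp_per_bond: float = 4.2
    atp_per_glucose: float = 26.0
    carbons_per_glucose: float = 6.0

    def __post_init__(self) -> None:
        if min(self.atp_per_bond, self.atp_per_glucose, self.carbons_per_glucose) <= 0:
            raise ValueError("all cost parameters must be positive")


def load_cost_table(path: str | None = None) -> pd.DataFrame:
    """Load an amino-acid cost table (columns: residue, atp_cost, n_carbon).

    With no path, loads the packaged synthetic example table (plausible
    relative magnitudes, *not* measured values).  Validates that all 20
    standard residues are present with non-negative costs and the standard
    carbon counts.
    """
    if path is None:
        with resources.files("cuephylo.data").joinpath(
            "amino_acid_costs_synthetic.tsv"
        ).open() as fh:
            table = pd.read_csv(fh, sep="\t", comment="#")
    else:
        table = pd.read_csv(path, sep="\t", comment="#")
    table = table.set_index("residue")
    missing = set(RESIDUE_CARBONS) - set(table.index)
    if missing:
        raise ValueError(f"cost table missing residues: {sorted(missing)}")
    if (table["atp_cost"] < 0).any():
        raise ValueError("atp_cost must be non-negative")
    for res, n_c in RESIDUE_CARBONS.items():
        if int(table.loc[res, "n_carbon"]) != n_c:
            raise ValueError(f"n_carbon for {res} must be {n_c}")
    return table


def _check_sequence(protein_seq: str) -> str:
    seq = protein_seq.strip().upper()
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - set(RESIDUE_CARBONS)
    if bad:
        raise ValueError(f"unknown residue symbols: {sorted(bad)}")
    return seq


def residue_carbons(protein_seq: str, table: pd.DataFrame | None = None) -> int:
    """Total carbon atoms in a protein (sum of per-residue carbons)."""
    seq = _check_sequence(protein_seq)
    carbons = (
        table["n_carbon"].to_dict() if table is not None else RESIDUE_CARBONS
    )
    return int(sum(carbons[a] for a in seq))


def protein_atp_cost(
    protein_seq: str, table: pd.DataFrame, params: CostParameters | None = None
) -> float:
    """ATP to build one protein: residue biosynthesis plus bond formation."""
    params = params or CostParameters()
    seq = _check_sequence(protein_seq)
    costs = table["atp_cost"].to_dict()
    return float(sum(costs[a] for a in seq) + params.atp_per_bond * (len(seq) - 1))


def protein_cue(
    protein_seq: str, table: pd.DataFrame, params: CostParameters | None = None
) -> float:
    """Per-protein theoretical C assimilation efficiency.

    The carbon respired to regenerate the ATP spent is
    ATP_total * carbons_per_glucose / atp_per_glucose; CUE is the protein's
    carbon over protein carbon plus respired carbon.
    """
    params = params or CostParameters()
    n_c = residue_carbons(protein_seq, table)
    atp = protein_atp_cost(protein_seq, table, params)
    c_respired = atp * params.carbons_per_glucose / params.atp_per_glucose
    return float(n_c / (n_c + c_respired))


# ---------------------------------------------------------------------------
# Codon bias and expression weights

@dataclasses.dataclass
class CodonBiasModel:
    """Relative adaptiveness per codon and CAI per gene.

    ``w`` maps each codon to its reference frequency divided by the highest
    frequency in its synonymous family (so the preferred codon has w = 1);
    CAI is the geometric mean of w over a gene's codons, excluding the
    non-degenerate Met and Trp families and stop codons.
    """

    w: dict[str, float]
    cai: pd.Series
    expression_weights: pd.Series


def _codon_counts(cds: str, gene_id: str = "") -> dict[str, int]:
    seq = cds.strip().upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length not divisible by 3: {gene_id or cds[:12]}")
    counts: dict[str, int] = {}
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        counts[codon] = counts.get(codon, 0) + 1
    return counts


def relative_adaptiveness(reference_cds: Mapping[str, str]) -> dict[str, float]:
    """Per-codon w from a reference (highly expressed) gene set.

    Codons unobserved in the reference are floored at 0.5 counts before
    normalising, so no codon gets w = 0.
    """
    if not reference_cds:
        raise ValueError("reference CDS set is empty")
    totals: dict[str, float] = {c: 0.0 for c in CODON_TABLE}
    for gid, seq in reference_cds.items():
        for codon, cnt in _codon_counts(seq, gid).items():
            if codon in totals:
                totals[codon] += cnt
    w: dict[str, float] = {}
    for fam in _SYNONYMOUS.values():
        counts = np.array([max(totals[c], 0.5) for c in fam])
        top = counts.max()
        for c, cnt in zip(fam, counts):
            w[c] = float(cnt / top)
    return w


def gene_cai(cds: str, w: Mapping[str, float], gene_id: str = "") -> float:
    """Codon adaptation index: geometric mean of w over informative codons.

    Met/Trp (single-codon families) and stop codons carry no information
    and are excluded; internal stop codons are skipped with a warning.
    """
    import warnings

    log_sum = 0.0
    n_used = 0
    seq = cds.strip().upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length not divisible by 3: {gene_id or cds[:12]}")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for j, codon in enumerate(codons):
        if codon in _STOPS:
            if j < len(codons) - 1:
                warnings.warn(f"internal stop codon in {gene_id or 'CDS'}; skipped")
            continue
        if codon not in CODON_TABLE:
            raise ValueError(f"invalid codon {codon!r} in {gene_id or 'CDS'}")
        if len(_SYNONYMOUS[CODON_TABLE[codon]]) == 1:
            continue
        log_sum += math.log(w[codon])
        n_used += 1
    if n_used == 0:
        return 1.0
    return float(math.exp(log_sum / n_used))


def codon_bias_weights(
    cds_set: Mapping[str, str], reference_cds: Mapping[str, str]
) -> CodonBiasModel:
    """CAI-based expression weights for a gene set.

    Weights are proportional to CAI and normalised to sum to 1 over the
    supplied genes.
    """
    w = relative_adaptiveness(reference_cds)
    cai = pd.Series(
        {gid: gene_cai(seq, w, gid) for gid, seq in cds_set.items()}, name="cai"
    )
    weights = cai / cai.sum()
    weights.name = "weight"
    return CodonBiasModel(w=w, cai=cai, expression_weights=weights)


@dataclasses.dataclass
class EnzymeCostResult:
    """Per-protein costs and the expression-weighted organism CUE."""

    per_protein: pd.DataFrame  # n_carbon, atp_total, cue_protein, cai, weight
    organism_cue: float


def organism_exoenzyme_cue(
    proteins: Mapping[str, str],
    cds: Mapping[str, str],
    table: pd.DataFrame,
    params: CostParameters | None = None,
    reference_cds: Mapping[str, str] | None = None,
) -> EnzymeCostResult:
    """Whole-exoenzyme production CUE for one organism.

    Per-protein CUEs are weighted by codon-bias-predicted relative
    expression; with no reference set the weights are uniform.  Protein and
    CDS ids must match, and each CDS must translate to its protein
    (trailing stop codons are tolerated).
    """
    params = params or CostParameters()
    if set(proteins) != set(cds):
        raise ValueError("protein and CDS ids do not match")
    ids = sorted(proteins)
    if reference_cds is not None:
        model = codon_bias_weights({g: cds[g] for g in ids}, reference_cds)
        cai = model.cai.reindex(ids)
        weights = model.expression_weights.reindex(ids)
    else:
        cai = pd.Series(np.nan, index=ids)
        weights = pd.Series(1.0 / len(ids), index=ids)
    rows = []
    for gid in ids:
        seq = proteins[gid].strip().upper()
        translated = str(Seq(cds[gid]).translate()).rstrip("*")
        if translated != seq:
            raise ValueError(f"CDS for {gid} does not translate to its protein")
        rows.append(
            {
                "protein": gid,
                "n_carbon": residue_carbons(seq, table),
                "atp_total": protein_atp_cost(seq, table, params),
                "cue_protein": protein_cue(seq, table, params),
            }
        )
    per = pd.DataFrame(rows).set_index("protein")
    per["cai"] = cai
    per["weight"] = weights
    organism = float(np.sum(per["cue_protein"] * per["weight"]))
    return EnzymeCostResult(per_protein=per, organism_cue=organism)


def keyword_filter(
    annotations: pd.Series, patterns: Sequence[str] = ("*rotease", "*roteinase",
                                                       "*eptidase", "*osphatase",
                                                       "*hospholipase"),
) -> pd.Index:
    """Ids whose annotation matches any extracellular-enzyme keyword pattern.

    A trivial shell-style string matcher over an annotation table; upstream
    signal-peptide or CAZyme classification is outside this package's scope.
    """
    mask = annotations.astype(str).str.lower().map(
        lambda s: any(fnmatch.fnmatch(s, p.lower() + "*") or fnmatch.fnmatch(s, "*" + p.lower())
                      for p in patterns)
    )
    return annotations.index[mask]
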