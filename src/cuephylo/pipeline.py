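"""End-to-end orchestration: simulate -> CUE -> Q10 -> signal -> markers.

A run is configured by a single YAML file (explicit seeds per stochastic
stage), writes plain TSV/CSV/Newick outputs into a run directory, and
records a manifest with SHA-256 hashes of every input and output so a rerun
with the same config is verifiably identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import growth_cue as gc
from . import markers as mk
from . import phylocomp as pc
from . import synthetic_data as sd
from . import temp_response as tr

__all__ = ["RunConfig", "run_pipeline", "make_report"]


DEFAULT_CONFIG: dict[str, Any] = {
    "output_dir": "cuephylo_run",
    "simulate": {
        "n_isolates": 10,
        "substrates": ["glucose", "pyruvate"],
        "temperatures": [15.0, 25.0],
        "n_replicates": 3,
        "tree_seed": 11,
        "trait_seed": 12,
        "growth_seed": 13,
        "genome_seed": 14,
        "n_kos": 150,
        "n_causal": 3,
    },
    "constants": {"biomass_per_od": 130.0, "culture_ml": 10.0, "headspace_ml": 25.0},
    "cue": {"min_points": 3, "max_points": 10,
            "respiration_method": "cumulative", "alpha": 0.05,
            "min_replicates": 2},
    "q10": {"n_boot": 1000, "boot_seed": 21},
    "phylosig": {"n_perm": 999, "perm_seed": 31, "bm_ci": False, "n_sim": 500},
    "markers": {"alpha": 0.05, "min_prevalence": 4, "explore_fraction": 0.65,
                "residual_seed": 41},
}


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration (see DEFAULT_CONFIG for the keys)."""

    raw: dict[str, Any]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls.from_dict(user)

    @classmethod
    def from_dict(cls, user: dict[str, Any]) -> "RunConfig":
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
        inputs = cfg.get("inputs", {})
        for name, p in inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input {name!r} missing: {p}")
        return cls(raw=cfg)

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulate_inputs(cfg: RunConfig, out: Path) -> dict[str, Path]:
    sim = cfg["simulate"]
    tree = sd.simulate_tree(sd.TreeSimParams(n_tips=sim["n_isolates"],
                                             seed=sim["tree_seed"]))
    tree_path = out / "tree.nwk"
    tree.write(path=str(tree_path), schema="newick")
    labels = sorted(t.label for t in tree.taxon_namespace)
    rng = np.random.default_rng(sim["growth_seed"])
    # Per-isolate ground truth traits evolve on the tree: log growth rate and
    # a CUE anchor, plus substrate and temperature offsets.
    mu_trait = sd.simulate_trait_bm(tree, sd.TraitSimParams(
        sigma2=0.04, root_value=np.log(0.25), seed=sim["trait_seed"]))
    cue_trait = sd.simulate_trait_bm(tree, sd.TraitSimParams(
        sigma2=0.003, root_value=0.55, seed=sim["trait_seed"] + 1))
    frames, truths = [], []
    for iso in labels:
        for sub_i, sub in enumerate(sim["substrates"]):
            for t_i, temp in enumerate(sim["temperatures"]):
                mu = float(np.exp(mu_trait[iso]) * (1.0 + 0.2 * t_i) * (1.0 - 0.1 * sub_i))
                cue = float(np.clip(cue_trait[iso] - 0.03 * sub_i - 0.02 * t_i, 0.15, 0.9))
                p = sd.GrowthSimParams(
                    mu_true=mu, cue_true=cue, temperature_c=float(temp),
                    seed=int(rng.integers(2**31 - 1)),
                    biomass_per_od=cfg["constants"]["biomass_per_od"],
                    culture_ml=cfg["constants"]["culture_ml"],
                    headspace_ml=cfg["constants"]["headspace_ml"],
                )
                curves, truth = sd.simulate_growth_experiment(
                    p, sim["n_replicates"], isolate=iso, substrate=sub)
                frames.append(curves)
                truths.append(truth)
    growth_path = out / "growth_curves.csv"
    pd.concat(frames, ignore_index=True).to_csv(growth_path, index=False)
    truth_path = out / "growth_truth.csv"
    pd.concat(truths, ignore_index=True).to_csv(truth_path, index=False)
    features, cue_g, causal = sd.simulate_genomes(tree, sd.GenomeSimParams(
        n_kos=sim["n_kos"], n_causal=sim["n_causal"], effect_size=0.05,
        seed=sim["genome_seed"]))
    feat_path = out / "genome_features.tsv"
    features.to_csv(feat_path, sep="\t")
    (out / "genome_truth.json").write_text(json.dumps({"causal_kos": causal}))
    return {"growth_csv": growth_path, "tree": tree_path, "features_tsv": feat_path}


def run_pipeline(config: RunConfig | dict | str) -> Path:
    """Execute the pipeline stages in dependency order.

    Returns the run directory; every stage writes its table there and the
    manifest records hashes, parameters and timings.  A stage failure
    raises with the stage name; earlier outputs remain on disk.
    """
    if isinstance(config, str):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__, "config": config.raw, "stages": {}, "files": {},
    }
    inputs = {k: Path(v) for k, v in config.raw.get("inputs", {}).items()}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage label
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        return deco

    if not inputs:
        @stage("simulate")
        def _():
            inputs.update(_simulate_inputs(config, out))

    constants = gc.AssayConstants(**config["constants"])

    @stage("cue")
    def _():
        curves = pd.read_csv(inputs["growth_csv"])
        ccfg = config["cue"]
        table = gc.estimate_cue_table(
            curves, constants, min_pts=ccfg["min_points"],
            max_pts=ccfg["max_points"],
            respiration_method=ccfg["respiration_method"], alpha=ccfg["alpha"])
        table.to_csv(out / "cue_replicates.tsv", sep="\t", index=False)
        kept = gc.qc_filter(table, min_replicates=ccfg["min_replicates"],
                            alpha=ccfg["alpha"])
        kept.to_csv(out / "cue_filtered.tsv", sep="\t", index=False)

    @stage("q10")
    def _():
        kept = pd.read_csv(out / "cue_filtered.tsv", sep="\t")
        qcfg = config["q10"]
        q10s = tr.q10_table(kept, n_boot=qcfg["n_boot"], seed=qcfg["boot_seed"])
        q10s.to_csv(out / "q10.tsv", sep="\t", index=False)

    @stage("phylosig")
    def _():
        kept = pd.read_csv(out / "cue_filtered.tsv", sep="\t")
        tree = pc.read_tree(str(inputs["tree"]))
        scfg = config["phylosig"]
        rows = []
        loo_rows = []
        for (sub, temp), grp in kept.groupby(["substrate", "temperature_c"]):
            mean_cue = grp.groupby("isolate")["cue"].mean()
            if len(mean_cue) < 4 or mean_cue.std() == 0:
                continue
            V, labels = pc.vcv_matrix(tree)
            common = [l for l in labels if l in mean_cue.index]
            if len(common) < 4:
                continue
            idx = [labels.index(l) for l in common]
            Vs = V[np.ix_(idx, idx)]
            res = pc.phylo_signal(Vs, mean_cue.loc[common],
                                  n_perm=scfg["n_perm"], seed=scfg["perm_seed"],
                                  bm_ci=scfg["bm_ci"], n_sim=scfg["n_sim"],
                                  labels=common)
            rows.append({
                "substrate": sub, "temperature_c": temp, "n": len(common),
                "k": res.k, "k_p": res.k_p, "lambda": res.lambda_hat,
                "lambda_p": res.lambda_p,
                "bm_ci_k_low": res.bm_ci_k[0] if res.bm_ci_k else np.nan,
                "bm_ci_k_high": res.bm_ci_k[1] if res.bm_ci_k else np.nan,
            })
            preds, summ = pc.predict_tip_loo(Vs, mean_cue.loc[common], labels=common)
            preds = preds.reset_index()
            preds.insert(0, "substrate", sub)
            preds.insert(1, "temperature_c", temp)
            loo_rows.append(preds)
        pd.DataFrame(rows).to_csv(out / "phylosig.tsv", sep="\t", index=False)
        if loo_rows:
            pd.concat(loo_rows, ignore_index=True).to_csv(
                out / "tip_predictions.tsv", sep="\t", index=False)

    if "features_tsv" in inputs:
        @stage("markers")
        def _():
            mcfg = config["markers"]
            tree = pc.read_tree(str(inputs["tree"]))
            features = pd.read_csv(inputs["features_tsv"], sep="\t", index_col=0)
            kept = pd.read_csv(out / "cue_filtered.tsv", sep="\t")
            glu = kept[kept["substrate"] == kept["substrate"].iloc[0]]
            cue = glu.groupby("isolate")["cue"].mean()
            dens = mk.standardize_density(features)
            taxa = [t for t in dens.index if t in cue.index]
            n_explore = max(6, int(len(taxa) * mcfg["explore_fraction"]))
            explore_taxa = taxa[:n_explore]
            cands = mk.explore_markers(tree, cue, dens.loc[taxa], explore_taxa,
                                       alpha=mcfg["alpha"],
                                       min_prevalence=mcfg["min_prevalence"])
            cands.to_csv(out / "marker_candidates.tsv", sep="\t")
            final, report = mk.finalize_markers(
                cands[cands["candidate"]].copy(), tree, cue, dens.loc[taxa],
                alpha=mcfg["alpha"], residual_seed=mcfg["residual_seed"])
            final.to_csv(out / "marker_final.tsv", sep="\t")
            pd.Series({
                "n_explore": report.n_explore,
                "n_full_glucose": report.n_full_glucose,
                "n_other_substrates": report.n_other_substrates,
                "n_microcosm": report.n_microcosm,
                "n_final": report.n_final,
            }).to_csv(out / "marker_summary.tsv", sep="\t", header=False)

    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][p.name] = _sha256(p)
    for name, p in inputs.items():
        manifest["files"][f"input:{name}"] = _sha256(Path(p))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def make_report(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Summary tables from completed stage outputs (pass-through, no
    recomputation): a signal table (substrate x temperature K/lambda grid),
    a Q10 table, and the marker tally if present."""
    run_dir = Path(run_dir)
    missing = [f for f in ("phylosig.tsv", "q10.tsv") if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing stage outputs: {missing}")
    report: dict[str, pd.DataFrame] = {}
    sig = pd.read_csv(run_dir / "phylosig.tsv", sep="\t")
    report["signal"] = sig.pivot_table(
        index="substrate", columns="temperature_c", values=["k", "lambda"])
    q10 = pd.read_csv(run_dir / "q10.tsv", sep="\t")
    cols = ["isolate", "substrate", "t_low", "t_high", "q10", "ci_low",
            "ci_high", "sensitive"]
    report["q10"] = q10[[c for c in cols if c in q10.columns]]
    marker_path = run_dir / "marker_summary.tsv"
    if marker_path.exists():
        report["markers"] = pd.read_csv(marker_path, sep="\t", header=None,
                                        names=["stage", "count"])
    for name, frame in report.items():
        frame.to_csv(run_dir / f"report_{name}.tsv", sep="\t")
    return report
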