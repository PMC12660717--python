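"""Pipeline orchestration: run stages in dependency order with provenance.

Every artifact written gets a JSON sidecar recording the config hash,
the root seed and the package version, so a rerun with an identical
config is verifiably identical.  All randomness flows from the single
root seed (the synthetic stage uses it directly; no other stage is
stochastic).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .circuits import enumerate_ffls, read_edge_list, summarize_census, write_motifs
from .config import RunConfig, config_hash
from .dynamics import simulate
from .patterns import (
    ContrastRecord,
    call_patterns_table,
    infer_tf_sign,
    assemble_putative_iffl,
)
from .phase import sweep
from .synth import (
    GENOTYPES,
    SyntheticDesign,
    _oxygen_contrast_table,
    generate_counts,
    standin_de,
)

__all__ = ["STAGES", "run_pipeline"]

#: Stages in dependency order.
STAGES = ("synth", "de", "classify", "infer", "simulate", "sweep")


def _write_sidecar(path: Path, config: RunConfig) -> None:
    meta = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "version": __version__,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}; run stage {producing_stage!r} first"
        )
    return path


def run_pipeline(config: RunConfig, stages: set[str] | None = None) -> list[Path]:
    """Run the requested stages; returns the artifact paths written."""
    requested = set(stages) if stages is not None else set(STAGES)
    bad = sorted(requested - set(STAGES))
    if bad:
        raise ValueError(
            f"unknown stage(s) {', '.join(bad)}; valid stages: {', '.join(STAGES)}"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> Path:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        _write_sidecar(path, config)
        written.append(path)
        return path

    if "synth" in requested:
        design = dataclasses.replace(config.synth, seed=config.seed)
        counts, samples, truth = generate_counts(design)
        emit(counts.reset_index(names="gene"), "counts.tsv")
        emit(samples, "samples.tsv")
        emit(truth, "truth.tsv")

    if "de" in requested:
        counts = pd.read_csv(_require(out / "counts.tsv", "synth"),
                             sep="\t", index_col="gene")
        samples = pd.read_csv(_require(out / "samples.tsv", "synth"), sep="\t")
        for g in GENOTYPES:
            emit(_oxygen_contrast_table(counts, samples, g), f"contrasts_{g}.tsv")
        cond = config.patterns.kd_condition
        for genotype in ("TP53KD", "NOTCH1KD"):
            a = samples.loc[(samples.genotype == genotype)
                            & (samples.condition == cond), "sample"].tolist()
            b = samples.loc[(samples.genotype == "WT")
                            & (samples.condition == cond), "sample"].tolist()
            de = standin_de(counts, samples, (a, b))
            de["contrast"] = f"KDvWT_{cond}"
            emit(de, f"kd_vs_wt_{genotype}.tsv")

    if "classify" in requested:
        calls = {}
        for g in GENOTYPES:
            table = pd.read_csv(_require(out / f"contrasts_{g}.tsv", "de"), sep="\t")
            calls[g] = call_patterns_table(table, alpha=config.patterns.alpha,
                                           genotype=g)
            emit(calls[g], f"patterns_{g}.tsv")
        wt = calls["WT"].set_index("gene")
        rows = []
        for tf, genotype in (("TP53", "TP53KD"), ("NOTCH1", "NOTCH1KD")):
            kd = calls[genotype].set_index("gene")
            for gene in wt.index:
                wt_pat = wt.at[gene, "pattern"]
                kd_pat = kd.at[gene, "pattern"]
                rows.append({
                    "gene": gene, "tf": tf, "wt_pattern": wt_pat,
                    "kd_pattern": kd_pat,
                    "disrupted": bool(wt.at[gene, "oscillation_specific"]
                                      and kd_pat != wt_pat),
                })
        emit(pd.DataFrame(rows), "tf_dependence.tsv")

    if "infer" in requested:
        dep = pd.read_csv(_require(out / "tf_dependence.tsv", "classify"), sep="\t")
        wt_contrasts = pd.read_csv(
            _require(out / "contrasts_WT.tsv", "de"), sep="\t")
        hvn = wt_contrasts[wt_contrasts.contrast == "HvN"].set_index("gene")
        cond = config.patterns.kd_condition
        motifs = []
        for tf, genotype in (("TP53", "TP53KD"), ("NOTCH1", "NOTCH1KD")):
            kd_de = pd.read_csv(
                _require(out / f"kd_vs_wt_{genotype}.tsv", "de"),
                sep="\t").set_index("gene")
            sub = dep[(dep.tf == tf) & dep.disrupted]
            for gene in sub["gene"]:
                sign = infer_tf_sign(
                    ContrastRecord(gene, f"KDvWT_{cond}",
                                   float(kd_de.at[gene, "log2fc"]),
                                   float(kd_de.at[gene, "padj"])),
                    alpha=config.patterns.alpha,
                )
                motif = assemble_putative_iffl(
                    gene, tf, sign,
                    ContrastRecord(gene, "HvN", float(hvn.at[gene, "log2fc"]),
                                   float(hvn.at[gene, "padj"])),
                    alpha=config.patterns.alpha,
                )
                if motif is not None:
                    motifs.append(motif)
        path = out / "putative_motifs.tsv"
        write_motifs(motifs, path)
        _write_sidecar(path, config)
        written.append(path)

    if "simulate" in requested:
        traj = simulate(config.circuit, config.protocol)
        emit(traj.to_frame(), "trajectory.tsv")

    if "sweep" in requested:
        diagram = sweep(
            config.circuit, grid_points=config.sweep.grid_points,
            k_range=(config.sweep.k_min, config.sweep.k_max),
            protocol=config.protocol, rel_tol=config.sweep.rel_tol,
        )
        emit(diagram.to_frame(), "phase_diagram.tsv")

    return written
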