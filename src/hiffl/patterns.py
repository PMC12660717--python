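"""Transcriptomic N/H/O pattern calling and TF-dependence inference.

The experimental arm of the pipeline: per-gene differential-expression
statistics from three oxygen contrasts (H vs N, O vs N, O vs H) are
turned into a total ordering of the normoxia / hypoxia / cycling-hypoxia
condition means, genes whose oscillation-specific wild-type ordering is
lost upon knockdown of a candidate intermediary TF (TP53 or NOTCH1) are
flagged as TF-dependent, the TF->gene regulatory sign is read off the
knockdown-vs-wild-type shift, and the pieces are assembled into putative
HIF-1-rooted feed-forward loops.

This module consumes contrast tables from any DE engine (the reference
analysis used DESeq2 with BH-adjusted p-values); it performs no count
modelling itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .circuits import FFLMotif, classify_ffl
from .phase import OSCILLATION_SPECIFIC, ORDER_LABELS

__all__ = [
    "OXYGEN_CONTRASTS",
    "NOT_SIGNIFICANT",
    "INCONSISTENT",
    "ContrastRecord",
    "GenePatternCall",
    "TFDependenceCall",
    "call_pattern",
    "call_patterns_table",
    "call_disruption",
    "infer_tf_sign",
    "assemble_putative_iffl",
    "read_contrasts",
]

OXYGEN_CONTRASTS = ("HvN", "OvN", "OvH")
KD_CONTRASTS = ("KDvWT_N", "KDvWT_H", "KDvWT_O")
NOT_SIGNIFICANT = "NOT_SIGNIFICANT"
INCONSISTENT = "INCONSISTENT"


@dataclass(frozen=True)
class ContrastRecord:
    """One gene's DE statistics in one contrast (log2FC of A vs B)."""

    gene: str
    contrast: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if self.contrast not in OXYGEN_CONTRASTS + KD_CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj must be in [0, 1], got {self.padj}")


@dataclass(frozen=True)
class GenePatternCall:
    """The N/H/O ordering called for one gene in one genotype."""

    gene: str
    genotype: str
    pattern: str  # an ORDER_LABELS entry, NOT_SIGNIFICANT, or INCONSISTENT
    significant: Mapping[str, bool]

    @property
    def oscillation_specific(self) -> bool:
        return self.pattern in OSCILLATION_SPECIFIC


@dataclass(frozen=True)
class TFDependenceCall:
    """TF-dependence verdict for one gene against one candidate TF."""

    gene: str
    tf: str
    wt_pattern: str
    kd_pattern: str
    disrupted: bool
    tf_to_gene_sign: int | None = None  # +1 activator, -1 repressor, None indeterminate


def call_pattern(
    records: Iterable[ContrastRecord],
    alpha: float = 0.05,
    genotype: str = "WT",
) -> GenePatternCall:
    """Derive the total N/H/O order of one gene from its three contrasts.

    Requires exactly the HvN, OvN and OvH records of a single gene.  The
    call is NOT_SIGNIFICANT unless all three adjusted p-values fall
    below ``alpha``; with three significant, signed fold changes the
    pairwise relations either admit a unique total order (one of the six
    labels) or are cyclic, reported as INCONSISTENT.
    """
    recs = {r.contrast: r for r in records}
    missing = [c for c in OXYGEN_CONTRASTS if c not in recs]
    if missing:
        raise ValueError(f"missing contrast(s): {', '.join(missing)}")
    genes = {r.gene for r in recs.values()}
    if len(genes) != 1:
        raise ValueError(f"records mix genes: {sorted(genes)}")
    gene = genes.pop()

    signif = {c: bool(recs[c].padj < alpha) for c in OXYGEN_CONTRASTS}
    if not all(signif.values()):
        return GenePatternCall(gene, genotype, NOT_SIGNIFICANT, signif)

    # Each contrast AvB with log2fc > 0 asserts A > B.  A strict total
    # order exists iff the win counts over {N, H, O} are {0, 1, 2}.
    wins = {"N": 0, "H": 0, "O": 0}
    pairs = {"HvN": ("H", "N"), "OvN": ("O", "N"), "OvH": ("O", "H")}
    for c, (a, b) in pairs.items():
        fc = recs[c].log2fc
        if fc > 0:
            wins[a] += 1
        elif fc < 0:
            wins[b] += 1
        else:  # exact zero cannot order the pair
            return GenePatternCall(gene, genotype, INCONSISTENT, signif)
    if sorted(wins.values()) != [0, 1, 2]:
        return GenePatternCall(gene, genotype, INCONSISTENT, signif)
    ordered = sorted(wins, key=wins.__getitem__)
    return GenePatternCall(gene, genotype, "<".join(ordered), signif)


def call_patterns_table(
    contrasts: pd.DataFrame,
    alpha: float = 0.05,
    genotype: str = "WT",
) -> pd.DataFrame:
    """Vectorized ``call_pattern`` over a long-format contrast table.

    ``contrasts`` needs columns gene, contrast, log2fc, padj with the
    three oxygen contrasts per gene.  Returns one row per gene with the
    called pattern and an oscillation-specific flag.
    """
    required = {"gene", "contrast", "log2fc", "padj"}
    if not required.issubset(contrasts.columns):
        raise ValueError(f"contrast table needs columns {sorted(required)}")
    wide_fc = contrasts.pivot_table(index="gene", columns="contrast",
                                    values="log2fc", aggfunc="first")
    wide_p = contrasts.pivot_table(index="gene", columns="contrast",
                                   values="padj", aggfunc="first")
    missing = [c for c in OXYGEN_CONTRASTS if c not in wide_fc.columns]
    if missing:
        raise ValueError(f"missing contrast(s): {', '.join(missing)}")
    rows = []
    for gene in wide_fc.index:
        recs = [
            ContrastRecord(gene, c, float(wide_fc.at[gene, c]), float(wide_p.at[gene, c]))
            for c in OXYGEN_CONTRASTS
        ]
        call = call_pattern(recs, alpha=alpha, genotype=genotype)
        rows.append({
            "gene": gene, "genotype": genotype, "pattern": call.pattern,
            "oscillation_specific": call.oscillation_specific,
        })
    return pd.DataFrame(rows)


def call_disruption(wt: GenePatternCall, kd: GenePatternCall) -> TFDependenceCall:
    """Is the wild-type oscillation-specific pattern lost in the knockdown?

    ``disrupted`` is True iff the wild-type pattern is one of the four
    oscillation-specific orderings and the knockdown call differs from
    it (a different ordering, loss of significance, or inconsistency).
    """
    if wt.gene != kd.gene:
        raise ValueError(f"gene mismatch: {wt.gene!r} vs {kd.gene!r}")
    disrupted = wt.oscillation_specific and kd.pattern != wt.pattern
    return TFDependenceCall(
        gene=wt.gene, tf=kd.genotype, wt_pattern=wt.pattern,
        kd_pattern=kd.pattern, disrupted=disrupted,
    )


def infer_tf_sign(kd_vs_wt: ContrastRecord, alpha: float = 0.05) -> int | None:
    """Infer the TF->gene regulatory sign from a knockdown-vs-WT contrast.

    A significant increase upon knockdown implies the TF represses the
    gene (-1); a significant decrease implies activation (+1); anything
    else is indeterminate (None).
    """
    if kd_vs_wt.contrast not in KD_CONTRASTS:
        raise ValueError(
            f"expected a KD-vs-WT contrast, got {kd_vs_wt.contrast!r}"
        )
    if kd_vs_wt.padj < alpha:
        if kd_vs_wt.log2fc > 0:
            return -1
        if kd_vs_wt.log2fc < 0:
            return +1
    return None


def assemble_putative_iffl(
    gene: str,
    tf: str,
    tf_sign: int | None,
    wt_hvn: ContrastRecord,
    alpha: float = 0.05,
    master: str = "HIF1A",
) -> FFLMotif | None:
    """Build a candidate (master, TF, gene) loop from inferred edge signs.

    The master->TF edge is fixed activating (both candidate TFs are
    HIF-1 activated); the direct master->gene sign is the sign of the
    significant wild-type H-vs-N fold change.  Returns None when either
    sign is unavailable.  The returned motif may be coherent — callers
    interested only in incoherent loops filter on ``is_incoherent``.
    """
    if tf_sign is None:
        return None
    if wt_hvn.contrast != "HvN":
        raise ValueError(f"expected the HvN contrast, got {wt_hvn.contrast!r}")
    if wt_hvn.padj >= alpha or wt_hvn.log2fc == 0:
        return None
    direct_sign = +1 if wt_hvn.log2fc > 0 else -1
    coherence, type_label = classify_ffl(+1, tf_sign, direct_sign)
    return FFLMotif(master, tf, gene, +1, tf_sign, direct_sign, coherence, type_label)


def read_contrasts(path: str | Path) -> pd.DataFrame:
    """Read a long-format contrast TSV (gene, contrast, log2fc, padj)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "contrast", "log2fc", "padj"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    return df
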