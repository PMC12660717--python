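"""Signed feed-forward-loop taxonomy and motif enumeration.

A feed-forward loop (FFL) is the three-node motif in which a regulator X
controls a target Z both directly (X->Z) and through an intermediary
transcription factor Y (X->Y->Z).  Every edge carries a regulatory sign
(+1 activation, -1 repression).  The loop is *coherent* when the direct
sign equals the product of the two indirect signs, and *incoherent*
otherwise.  Within each coherence class the four possible sign triples
are numbered 1-4; the triple is always read in the order
(X->Y, Y->Z, X->Z).

This module enumerates FFLs rooted at a master regulator (HIF-1 in the
hypoxia setting) over a signed edge list such as a TRRUST or IPA export,
classifies each motif, and summarizes the census by coherence and type.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SignedEdge",
    "FFLMotif",
    "FFLCensus",
    "classify_ffl",
    "enumerate_ffls",
    "summarize_census",
    "read_edge_list",
    "write_motifs",
]

#: Sign-triple -> type number within each coherence class, triples ordered
#: (X->Y, Y->Z, X->Z).
INCOHERENT_TYPES = {
    (+1, -1, +1): 1,
    (-1, -1, -1): 2,
    (+1, +1, -1): 3,
    (-1, +1, +1): 4,
}
COHERENT_TYPES = {
    (+1, +1, +1): 1,
    (-1, -1, +1): 2,
    (+1, -1, -1): 3,
    (-1, +1, -1): 4,
}

_SIGN_TOKENS = {
    "+1": +1, "1": +1, "+": +1, "activation": +1, "activate": +1, "act": +1,
    "-1": -1, "−1": -1, "-": -1, "−": -1,
    "repression": -1, "repress": -1, "rep": -1, "inhibition": -1,
}


def _check_sign(s: int, name: str) -> int:
    if s not in (+1, -1):
        raise ValueError(f"{name} must be +1 or -1, got {s!r}")
    return s


@dataclass(frozen=True)
class SignedEdge:
    """One signed regulatory interaction source -> target."""

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop rejected: {self.source!r}")
        _check_sign(self.sign, "sign")


@dataclass(frozen=True)
class FFLMotif:
    """A classified feed-forward loop (x, y, z) with its three edge signs."""

    x: str
    y: str
    z: str
    sign_xy: int
    sign_yz: int
    sign_xz: int
    coherence: str
    type_label: int

    @property
    def is_incoherent(self) -> bool:
        return self.coherence == "incoherent"


def classify_ffl(sign_xy: int, sign_yz: int, sign_xz: int) -> tuple[str, int]:
    """Classify a sign triple into (coherence, type number).

    The loop is coherent iff ``sign_xz == sign_xy * sign_yz``; the type
    number follows the standard numbering of the four triples within each
    class, e.g. incoherent type 1 is (+, -, +) and incoherent type 3 is
    (+, +, -).
    """
    sign_xy = _check_sign(sign_xy, "sign_xy")
    sign_yz = _check_sign(sign_yz, "sign_yz")
    sign_xz = _check_sign(sign_xz, "sign_xz")
    triple = (sign_xy, sign_yz, sign_xz)
    if sign_xz == sign_xy * sign_yz:
        return "coherent", COHERENT_TYPES[triple]
    return "incoherent", INCOHERENT_TYPES[triple]


def _build_adjacency(
    network: Iterable[SignedEdge], conflict: str
) -> dict[str, dict[str, tuple[int, ...]]]:
    """source -> target -> tuple of distinct signs (len>1 only with keep-both)."""
    if conflict not in ("error", "keep-both"):
        raise ValueError(f"conflict policy must be 'error' or 'keep-both', got {conflict!r}")
    adj: dict[str, dict[str, set[int]]] = {}
    for e in network:
        adj.setdefault(e.source, {}).setdefault(e.target, set()).add(e.sign)
    out: dict[str, dict[str, tuple[int, ...]]] = {}
    for src, targets in adj.items():
        out[src] = {}
        for tgt, signs in targets.items():
            if len(signs) > 1 and conflict == "error":
                raise ValueError(
                    f"conflicting signs for edge {src}->{tgt}; "
                    "use conflict='keep-both' to keep one motif per sign"
                )
            out[src][tgt] = tuple(sorted(signs, reverse=True))
    return out


def enumerate_ffls(
    network: Iterable[SignedEdge],
    master: str,
    conflict: str = "error",
) -> list[FFLMotif]:
    """Enumerate every FFL (master, Y, Z) rooted at ``master``.

    A motif requires the three edges master->Y, Y->Z and master->Z with
    master, Y, Z pairwise distinct; Y is therefore always itself a
    regulator.  Duplicate identically-signed edges are collapsed;
    sign conflicts on one edge raise unless ``conflict='keep-both'``,
    which emits one motif per sign combination.  Output is sorted by
    (Y, Z) so enumeration order is deterministic.
    """
    adj = _build_adjacency(network, conflict)
    master_out = adj.get(master, {})
    motifs: list[FFLMotif] = []
    for y in sorted(master_out):
        if y == master:
            continue
        for z in sorted(adj.get(y, {})):
            if z == master or z == y or z not in master_out:
                continue
            for s_xy in master_out[y]:
                for s_yz in adj[y][z]:
                    for s_xz in master_out[z]:
                        coherence, type_label = classify_ffl(s_xy, s_yz, s_xz)
                        motifs.append(
                            FFLMotif(master, y, z, s_xy, s_yz, s_xz, coherence, type_label)
                        )
    return motifs


@dataclass(frozen=True)
class FFLCensus:
    """Counts and within-class percentage fractions per (coherence, type)."""

    counts: dict[tuple[str, int], int]
    fractions: dict[tuple[str, int], float]  # percent, 1 decimal; NaN if class empty

    def class_total(self, coherence: str) -> int:
        return sum(v for (c, _), v in self.counts.items() if c == coherence)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"coherence": c, "type": t, "count": self.counts[(c, t)],
             "percent": self.fractions[(c, t)]}
            for c in ("coherent", "incoherent")
            for t in (1, 2, 3, 4)
        ]
        return pd.DataFrame(rows)


def summarize_census(motifs: Iterable[FFLMotif]) -> FFLCensus:
    """Tally motifs per (coherence, type) with percent fractions within class.

    Fractions are percentages of the motif count within each coherence
    class, rounded to one decimal; an empty class yields NaN fractions.
    """
    tally = Counter((m.coherence, m.type_label) for m in motifs)
    counts = {(c, t): tally.get((c, t), 0)
              for c in ("coherent", "incoherent") for t in (1, 2, 3, 4)}
    fractions: dict[tuple[str, int], float] = {}
    for c in ("coherent", "incoherent"):
        total = sum(counts[(c, t)] for t in (1, 2, 3, 4))
        for t in (1, 2, 3, 4):
            fractions[(c, t)] = (
                round(100.0 * counts[(c, t)] / total, 1) if total else math.nan
            )
    return FFLCensus(counts=counts, fractions=fractions)


def parse_sign(token: object) -> int | None:
    """Map a TRRUST/IPA-style sign token to +1/-1; None for Unknown rows."""
    text = str(token).strip().lower()
    if text in ("unknown", "nan", ""):
        return None
    if text in _SIGN_TOKENS:
        return _SIGN_TOKENS[text]
    raise ValueError(f"unrecognized regulatory sign {token!r}")


def read_edge_list(path: str | Path) -> list[SignedEdge]:
    """Read a signed edge list TSV (source, target, sign).

    Accepts +1/-1, +/-, or Activation/Repression sign tokens, with or
    without a header line; rows with sign Unknown are dropped and counted
    in the log.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected at least 3 columns (source, target, sign)")
    first = str(df.iloc[0, 2]).strip().lower()
    if first in ("sign", "mode", "regulation", "interaction"):
        df = df.iloc[1:]
    edges: list[SignedEdge] = []
    dropped = 0
    for _, row in df.iterrows():
        sign = parse_sign(row.iloc[2])
        if sign is None:
            dropped += 1
            continue
        edges.append(SignedEdge(str(row.iloc[0]).strip(), str(row.iloc[1]).strip(), sign))
    if dropped:
        logger.info("dropped %d edges with Unknown sign from %s", dropped, path)
    return edges


def write_motifs(motifs: Iterable[FFLMotif], path: str | Path) -> None:
    """Write motifs as a TSV with one row per classified loop."""
    df = pd.DataFrame(
        [
            {"x": m.x, "y": m.y, "z": m.z, "sign_xy": m.sign_xy,
             "sign_yz": m.sign_yz, "sign_xz": m.sign_xz,
             "coherence": m.coherence, "type": m.type_label}
            for m in motifs
        ],
        columns=["x", "y", "z", "sign_xy", "sign_yz", "sign_xz", "coherence", "type"],
    )
    df.to_csv(path, sep="\t", index=False)
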