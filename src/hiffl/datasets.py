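"""Synthetic example networks.

The curated HIF-1 feed-forward-loop list used in the reference analysis
is distributed as journal supplementary data and is not redistributed
here.  ``synthetic_hif_ffl_network`` builds a synthetic stand-in edge
list whose HIF1A-rooted census reproduces the published marginals (31
incoherent loops split 18/0/12/1 over types 1-4 and 40 coherent loops
split 31/0/9/0); gene names are placeholders, so the network is suitable
for exercising and validating the enumeration/census machinery but
carries no biological content.
"""

from __future__ import annotations

from .circuits import INCOHERENT_TYPES, COHERENT_TYPES, SignedEdge

__all__ = ["synthetic_hif_ffl_network"]

#: Published census marginals: loops per type 1-4 within each class.
IFFL_TYPE_COUNTS = (18, 0, 12, 1)
CFFL_TYPE_COUNTS = (31, 0, 9, 0)


def synthetic_hif_ffl_network(
    iffl_counts: tuple[int, int, int, int] = IFFL_TYPE_COUNTS,
    cffl_counts: tuple[int, int, int, int] = CFFL_TYPE_COUNTS,
    master: str = "HIF1A",
) -> list[SignedEdge]:
    """Edge list realizing exactly the requested per-type loop counts.

    Each loop gets its own intermediary/target pair, so no unintended
    triples arise and the census of the returned network is the input
    counts by construction.
    """
    triples = {("incoherent", t): s for s, t in INCOHERENT_TYPES.items()}
    triples |= {("coherent", t): s for s, t in COHERENT_TYPES.items()}
    edges: list[SignedEdge] = []
    k = 0
    for coherence, counts in (("incoherent", iffl_counts),
                              ("coherent", cffl_counts)):
        for type_label, n in zip((1, 2, 3, 4), counts):
            s_xy, s_yz, s_xz = triples[(coherence, type_label)]
            for _ in range(n):
                y, z = f"TF{k:03d}", f"TARGET{k:03d}"
                edges.append(SignedEdge(master, y, s_xy))
                edges.append(SignedEdge(y, z, s_yz))
                edges.append(SignedEdge(master, z, s_xz))
                k += 1
    return edges
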