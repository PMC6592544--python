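"""Similarity graphs over significant hits: clusters and public sequences.

Vertices are significant hit clonotypes; edges join amino-acid CDR3s of the
same length differing by at most one substitution.  Within a sample, edges
additionally require the same VJ class (consistent with the per-VJ
statistics); across samples only the CDR3 is compared by default, so
convergent responses in different individuals join one cluster.  Connected
components of this graph are the sequence clusters used for motif analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .core import HitRecord
from .seqs import is_neighbor


@dataclass(frozen=True)
class HitVertex:
    sample_id: str
    sigma: str
    v_gene: str
    j_gene: str


def build_hit_graph(
    hits_by_sample: Mapping[str, Sequence[HitRecord]],
    cross_vj: bool = True,
    significant_only: bool = True,
) -> nx.Graph:
    """Build the undirected similarity graph over significant hits.

    ``cross_vj=True`` compares only the CDR3 for pairs from different
    samples (within-sample pairs always require matching VJ);
    ``cross_vj=False`` demands matching VJ everywhere.  The graph is simple:
    no self-loops, no multi-edges.
    """
    g = nx.Graph()
    vertices: list[HitVertex] = []
    for sample_id, hits in hits_by_sample.items():
        for h in hits:
            if significant_only and not h.significant:
                continue
            v = HitVertex(sample_id, h.sigma, h.v_gene, h.j_gene)
            if v not in g:
                g.add_node(v, degree_zero=True)
                vertices.append(v)
    for i, a in enumerate(vertices):
        for b in vertices[i + 1 :]:
            same_sample = a.sample_id == b.sample_id
            if same_sample or not cross_vj:
                if (a.v_gene, a.j_gene) != (b.v_gene, b.j_gene):
                    continue
            if is_neighbor(a.sigma, b.sigma):
                g.add_edge(a, b)
    for v in g.nodes:
        g.nodes[v]["degree_zero"] = g.degree(v) == 0
    return g


def connected_components(g: nx.Graph) -> list[list[HitVertex]]:
    """Connected components, each sorted, ordered by smallest member."""
    comps = [
        sorted(c, key=lambda v: (v.sigma, v.v_gene, v.j_gene, v.sample_id))
        for c in nx.connected_components(g)
    ]
    comps.sort(key=lambda c: (c[0].sigma, c[0].v_gene, c[0].j_gene, c[0].sample_id))
    return comps


def public_hits(hits_by_sample: Mapping[str, Sequence[HitRecord]]) -> pd.DataFrame:
    """Hits shared across samples under exact (CDR3aa, V, J) identity.

    Returns one row per (sigma, v, j) found significant in at least two
    samples, with per-sample presence flags and the number of samples.
    """
    if len(hits_by_sample) < 2:
        raise ValueError("public-hit analysis needs at least two samples")
    samples = sorted(hits_by_sample)
    presence: dict[tuple[str, str, str], set[str]] = {}
    for sample_id, hits in hits_by_sample.items():
        for h in hits:
            if h.significant:
                presence.setdefault((h.sigma, h.v_gene, h.j_gene), set()).add(sample_id)
    rows = []
    for (sigma, v, j), found_in in sorted(presence.items()):
        if len(found_in) < 2:
            continue
        row = {"sigma": sigma, "v": v, "j": j, "n_samples": len(found_in)}
        for s in samples:
            row[f"in_{s}"] = s in found_in
        rows.append(row)
    cols = ["sigma", "v", "j", "n_samples"] + [f"in_{s}" for s in samples]
    return pd.DataFrame(rows, columns=cols)


def export_graph(g: nx.Graph, out_dir: str | Path, prefix: str = "hits") -> None:
    """Write GraphML, an edge-list TSV, and a components TSV with cluster ids.

    Zero-degree vertices are retained (flagged ``degree_zero``); figures hide
    them, exports do not.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    relabeled = nx.relabel_nodes(
        g, {v: f"{v.sample_id}|{v.sigma}|{v.v_gene}|{v.j_gene}" for v in g.nodes}
    )
    nx.write_graphml(relabeled, out_dir / f"{prefix}.graphml")
    with open(out_dir / f"{prefix}_edges.tsv", "w") as fh:
        fh.write("sample_a\tsigma_a\tv_a\tj_a\tsample_b\tsigma_b\tv_b\tj_b\n")
        for a, b in sorted(
            g.edges, key=lambda e: (e[0].sigma, e[1].sigma, e[0].sample_id)
        ):
            fh.write(
                f"{a.sample_id}\t{a.sigma}\t{a.v_gene}\t{a.j_gene}\t"
                f"{b.sample_id}\t{b.sigma}\t{b.v_gene}\t{b.j_gene}\n"
            )
    rows = []
    for cid, comp in enumerate(connected_components(g)):
        for v in comp:
            rows.append(
                {
                    "cluster": cid,
                    "sample": v.sample_id,
                    "sigma": v.sigma,
                    "v": v.v_gene,
                    "j": v.j_gene,
                    "cluster_size": len(comp),
                    "degree_zero": g.nodes[v]["degree_zero"],
                }
            )
    pd.DataFrame(
        rows,
        columns=["cluster", "sample", "sigma", "v", "j", "cluster_size", "degree_zero"],
    ).to_csv(out_dir / f"{prefix}_components.tsv", sep="\t", index=False)
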