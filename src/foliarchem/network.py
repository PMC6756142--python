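"""Consensus-spectrum clustering and the molecular network.

Replicate spectra of one molecule are merged into a consensus spectrum — the
"compound", the node of the molecular network.  Compounds are then scored
pairwise by (modified) cosine and connected when the score reaches the
network threshold, 0.6 by default; compounds similar to nothing remain
singleton nodes.  The same module houses blank-based contaminant removal for
feature tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError
from .spectra import Spectrum, cosine_score

__all__ = [
    "Compound",
    "MolecularNetwork",
    "cluster_spectra",
    "build_network",
    "component_summary",
    "subtract_blanks",
]

log = logging.getLogger(__name__)


@dataclass
class Compound:
    """Consensus spectrum representing one unique molecule.

    ``precursor_mz`` is the intensity-weighted mean of the member spectra's
    precursors (weight = member total ion intensity); ``consensus`` holds the
    tolerance-merged, intensity-summed member peaks.
    """

    id: str
    consensus: Spectrum
    member_ids: list[str] = field(default_factory=list)

    @property
    def precursor_mz(self) -> float:
        return self.consensus.precursor_mz


def _merge_peaks(mz: np.ndarray, intensity: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge peaks closer than ``tol`` into intensity-weighted mean positions."""
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    out_mz: list[float] = []
    out_it: list[float] = []
    acc_m, acc_i = mz[0] * intensity[0], intensity[0]
    last = mz[0]
    for m, i in zip(mz[1:], intensity[1:]):
        if m - last <= tol:
            acc_m += m * i
            acc_i += i
        else:
            out_mz.append(acc_m / acc_i)
            out_it.append(acc_i)
            acc_m, acc_i = m * i, i
        last = m
    out_mz.append(acc_m / acc_i)
    out_it.append(acc_i)
    return np.asarray(out_mz), np.asarray(out_it)


def cluster_spectra(spectra: Sequence[Spectrum], cluster_threshold: float = 0.95,
                    precursor_tol: float = 0.02, fragment_tol: float = 0.02,
                    intensity_power: float = 0.5) -> tuple[list[Compound], dict[str, str]]:
    """Greedy single-pass clustering of spectra into consensus compounds.

    Each spectrum joins the first existing compound whose precursor m/z lies
    within ``precursor_tol`` and whose consensus cosine is at least
    ``cluster_threshold`` (no precursor-shift matching: cluster identity
    means the same molecule); otherwise it founds a new compound.  Consensus
    peaks are the tolerance-merged, intensity-summed member peaks; the
    consensus precursor is the intensity-weighted mean over members.

    Returns the compound list and a spectrum-id → compound-id assignment.
    An empty input yields empty outputs.
    """
    if not 0 < cluster_threshold <= 1:
        raise InputError("cluster_threshold must be in (0, 1]")
    if precursor_tol <= 0 or fragment_tol <= 0:
        raise InputError("tolerances must be > 0")

    compounds: list[Compound] = []
    # parallel arrays for the precursor gate
    precursors: list[float] = []
    weights: list[float] = []  # summed member total intensities
    assignment: dict[str, str] = {}

    for sp in spectra:
        target = None
        for idx, comp in enumerate(compounds):
            if abs(sp.precursor_mz - precursors[idx]) > precursor_tol:
                continue
            score = cosine_score(comp.consensus, sp, fragment_tol=fragment_tol,
                                 intensity_power=intensity_power,
                                 allow_precursor_shift=False)
            if score >= cluster_threshold:
                target = idx
                break
        if target is None:
            cid = f"CC{len(compounds):05d}"
            consensus = Spectrum(id=cid, precursor_mz=sp.precursor_mz,
                                 mz=sp.mz.copy(), intensity=sp.intensity.copy())
            compounds.append(Compound(id=cid, consensus=consensus, member_ids=[sp.id]))
            precursors.append(sp.precursor_mz)
            weights.append(sp.total_intensity)
            assignment[sp.id] = cid
        else:
            comp = compounds[target]
            mz = np.concatenate([comp.consensus.mz, sp.mz])
            it = np.concatenate([comp.consensus.intensity, sp.intensity])
            m_mz, m_it = _merge_peaks(mz, it, fragment_tol)
            w_new = sp.total_intensity
            prec = (precursors[target] * weights[target] + sp.precursor_mz * w_new) / (
                weights[target] + w_new)
            precursors[target] = prec
            weights[target] += w_new
            comp.consensus = Spectrum(id=comp.id, precursor_mz=prec, mz=m_mz, intensity=m_it)
            comp.member_ids.append(sp.id)
            assignment[sp.id] = comp.id
    return compounds, assignment


@dataclass
class MolecularNetwork:
    """Undirected compound graph; edge (i, j, score) kept iff score >= threshold."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    score_threshold: float = 0.6

    def __post_init__(self) -> None:
        seen = set()
        for i, j, s in self.edges:
            if i == j:
                raise InputError(f"self-edge on node {i!r}")
            if s < self.score_threshold:
                raise InputError(f"edge ({i},{j}) score {s} below threshold")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise InputError(f"duplicate edge {key}")
            seen.add(key)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges, weight="score")
        return g

    def css_matrix(self, compound_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Chemical structural similarity matrix: 1 on the diagonal, the edge
        cosine off-diagonal where an edge exists, 0 elsewhere."""
        ids = list(compound_ids) if compound_ids is not None else list(self.nodes)
        pos = {c: k for k, c in enumerate(ids)}
        m = np.eye(len(ids))
        for i, j, s in self.edges:
            if i in pos and j in pos:
                m[pos[i], pos[j]] = s
                m[pos[j], pos[i]] = s
        return pd.DataFrame(m, index=ids, columns=ids)

    def write_edgelist(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("node_i\tnode_j\tscore\n")
            for i, j, s in sorted(self.edges):
                fh.write(f"{i}\t{j}\t{s:.6f}\n")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


def build_network(compounds: Sequence[Compound], fragment_tol: float = 0.02,
                  score_threshold: float = 0.6, intensity_power: float = 0.5,
                  allow_precursor_shift: bool = True) -> MolecularNetwork:
    """All-pairs cosine scoring of consensus spectra, thresholded inclusively.

    Precursor-shift (modified cosine) matching is on by default: network
    edges represent structural-analog relations, not identity.  Every
    compound appears as a node; those below threshold against all others are
    degree-0 singletons.
    """
    if not 0 <= score_threshold <= 1:
        raise InputError("score_threshold must be in [0, 1]")
    nodes = [c.id for c in compounds]
    edges: list[tuple[str, str, float]] = []
    for a in range(len(compounds)):
        ca = compounds[a]
        for b in range(a + 1, len(compounds)):
            s = cosine_score(ca.consensus, compounds[b].consensus,
                             fragment_tol=fragment_tol,
                             intensity_power=intensity_power,
                             allow_precursor_shift=allow_precursor_shift)
            if s >= score_threshold:
                edges.append((ca.id, compounds[b].id, s))
    return MolecularNetwork(nodes=nodes, edges=edges, score_threshold=score_threshold)


def component_summary(net: MolecularNetwork) -> tuple[list[int], int]:
    """Sizes of connected components with >= 2 nodes, plus singleton count.

    The sizes (descending) and the singleton count partition the node set:
    ``sum(sizes) + singletons == len(net.nodes)``.
    """
    g = net.to_networkx()
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    singletons = sum(1 for s in sizes if s == 1)
    return [s for s in sizes if s >= 2], singletons


def subtract_blanks(table: pd.DataFrame, meta: pd.DataFrame,
                    min_blank_intensity: float = 0.0) -> pd.DataFrame:
    """Remove laboratory-contaminant compounds using blank samples.

    Any compound whose intensity is >= ``min_blank_intensity`` (and positive)
    in ANY blank sample is dropped from the table; blank rows are dropped
    from the output.  With no blanks flagged the table is returned unchanged
    with a logged warning.
    """
    blanks = meta.loc[meta["sample_type"] == "blank", "sample_id"]
    blanks = [b for b in blanks if b in table.index]
    if not blanks:
        log.warning("no blank samples flagged; blank subtraction skipped")
        return table
    blk = table.loc[blanks]
    thresh = max(min_blank_intensity, np.finfo(float).tiny)
    contaminated = blk.columns[(blk >= thresh).any(axis=0)]
    out = table.drop(index=blanks).drop(columns=contaminated)
    log.info("blank subtraction removed %d compounds", len(contaminated))
    return out
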