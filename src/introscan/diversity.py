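"""Nucleotide diversity tracks and neighbor-joining trees.

Per-site nucleotide diversity (pi) is the average pairwise difference
between the called alleles at a site, computed with the standard
sample-size correction: with n called alleles at frequencies p_i,

    pi = n / (n - 1) * (1 - sum(p_i ** 2))

Windowed per-base pi divides the summed site values by the window width in
bases, treating every base without a variant record as monomorphic.

Sample relatedness uses identity-by-state (IBS) distance — one minus the
mean fraction of shared alleles over co-called sites — and the tree is
built with the Saitou-Nei neighbor-joining agglomeration, with
lexicographic tie-breaking so results are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .variants import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with named samples."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < 0).any():
            raise ValueError("negative distances")


@dataclass
class PiTrack:
    """Per-window per-base nucleotide diversity along one chromosome."""

    chrom: str
    window: int
    seq_length: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("negative pi")
        if len(self.values) != math.ceil(self.seq_length / self.window):
            raise ValueError("windows do not tile the chromosome")


def site_pi(column: np.ndarray) -> float:
    """Nucleotide diversity of one biallelic site from genotype codes.

    Equals the mean pairwise difference over all pairs of called alleles.
    Raises if fewer than two alleles are called.
    """
    column = np.asarray(column)
    called = column[column != MISSING]
    n = 2 * called.size
    if n < 2:
        raise ValueError("site has fewer than two called alleles")
    p_alt = float(np.sum(called)) / n
    return n / (n - 1) * (1.0 - p_alt**2 - (1.0 - p_alt) ** 2)


def windowed_pi(
    matrix: GenotypeMatrix, window: int, seq_lengths: dict[str, int] | None = None
) -> list[PiTrack]:
    """Per-base pi in fixed windows; invariant bases contribute zero.

    The denominator is the full window width, so the values are per-base
    averages over all bases, not only the variant positions.  Chromosome
    lengths default to the last variant position seen.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for site, col in zip(matrix.sites, matrix.genotypes):
        called = col[col != MISSING]
        if called.size < 1 or 2 * called.size < 2:
            continue
        by_chrom.setdefault(site.chrom, []).append((site.pos, site_pi(col)))
    tracks = []
    for chrom, entries in by_chrom.items():
        length = (seq_lengths or {}).get(chrom) or max(p for p, _ in entries)
        n_win = math.ceil(length / window)
        sums = np.zeros(n_win)
        for pos, pi in entries:
            sums[(pos - 1) // window] += pi
        tracks.append(
            PiTrack(chrom=chrom, window=window, seq_length=length, values=sums / window)
        )
    return tracks


def ibs_distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Identity-by-state distances between all sample pairs.

    distance(a, b) = 1 - mean over co-called sites of
    (shared alleles between the two genotypes / 2); for alt-dosage codes
    this is mean(|dose_a - dose_b|) / 2.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    gt = matrix.genotypes.astype(float)
    gt[matrix.genotypes == MISSING] = np.nan
    n = matrix.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(gt[:, i] - gt[:, j])
            ok = ~np.isnan(diff)
            if not ok.any():
                raise ValueError(
                    f"samples {matrix.samples[i]!r} and {matrix.samples[j]!r} "
                    "share no co-called sites"
                )
            d[i, j] = d[j, i] = float(np.mean(diff[ok])) / 2.0
    return DistanceMatrix(list(matrix.samples), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted tree in newick.

    At each step the pair minimizing Q(i, j) = (r - 2) d(i, j) - R_i - R_j
    is joined; among equal-Q pairs the lexicographically smallest pair of
    node labels is taken so the output is deterministic.  Branch lengths
    follow the standard formulas and may be clamped at zero.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least three taxa")
    nodes: dict[str, _Node] = {i: _Node(i) for i in dm.ids}
    d: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((dm.ids[i], dm.ids[j]))] = float(dm.values[i, j])
    active = sorted(dm.ids)
    counter = 0
    while len(active) > 3:
        r = len(active)
        row_sums = {
            a: sum(d[frozenset((a, b))] for b in active if b != a) for a in active
        }
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                a, b = active[ii], active[jj]
                q = (r - 2) * d[frozenset((a, b))] - row_sums[a] - row_sums[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dij = d[frozenset((a, b))]
        la = 0.5 * dij + (row_sums[a] - row_sums[b]) / (2 * (r - 2))
        lb = dij - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new_label = f"_nj{counter}"
        counter += 1
        nodes[new_label] = _Node(new_label, [(nodes[a], la), (nodes[b], lb)])
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new_label, c))] = 0.5 * (
                d[frozenset((a, c))] + d[frozenset((b, c))] - dij
            )
        active = sorted(set(active) - {a, b} | {new_label})
    # Final three nodes join at an unresolved (trifurcating) root.
    a, b, c = active
    dab = d[frozenset((a, b))]
    dac = d[frozenset((a, c))]
    dbc = d[frozenset((b, c))]
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    root = _Node("", [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return root.newick() + ";"
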