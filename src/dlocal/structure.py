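"""Structure-conserved SINE detection with single-exemplar covariance models.

B1 and B2 SINE retrotransposons fold into long hairpins; matches that
conserve the *structure* (not just the sequence) are found by building a
covariance model — a profile stochastic context-free grammar — from one
canonical sequence plus its dot-bracket secondary structure, and aligning
candidate windows to the model by CYK-style max dynamic programming over
the guide tree.  Scores are log2-odds ("bits") against a uniform null;
a window passes at the model's bitscore cutoff (50 for B1, 35 for B2).

Model anatomy: one PAIR node per base pair (16-entry pair emission table),
one LEFT node per unpaired base (4-entry table), BIF nodes at multiloop
branch points, END nodes at hairpin loops/segment ends.  Emissions are
pseudocount-smoothed log-odds centered on the exemplar bases; insertions
carry affine costs (open + extend per run) and node deletions are charged
open + extend per emitted base of the node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from numba import njit

from .motifs import encode_rna

NEG = -1e18

END, PAIR, LEFT, BIF = 0, 1, 2, 3

B1_CUTOFF = 50.0
B2_CUTOFF = 35.0


@dataclass(frozen=True)
class StructureExemplar:
    name: str
    sequence: str
    structure: str
    cutoff: float

    def __post_init__(self):
        if len(self.sequence) != len(self.structure):
            raise ValueError(f"{self.name}: sequence/structure length mismatch")
        _match_map(self.structure)  # raises on unbalanced brackets


@dataclass(frozen=True)
class StructureHit:
    gene_id: str
    model: str
    start: int
    end: int
    bitscore: float
    passes: bool


def _match_map(structure: str) -> dict[int, int]:
    """Map of '(' position -> matching ')' position; validates balance."""
    stack, match = [], {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            match[stack.pop()] = i
        elif ch != ".":
            raise ValueError(f"bad structure character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return match


def load_exemplar(name: str) -> StructureExemplar:
    """Load a packaged exemplar ('b1' or 'b2') from its FASTA + dot-bracket."""
    cutoff = {"b1": B1_CUTOFF, "b2": B2_CUTOFF}[name.lower()]
    data = resources.files("dlocal.data")
    fa = (data / f"{name.lower()}.fasta").read_text().splitlines()
    seq = "".join(ln.strip() for ln in fa if not ln.startswith(">"))
    db = (data / f"{name.lower()}.dotbracket").read_text().strip()
    return StructureExemplar(name.upper(), seq, db, cutoff)


@dataclass
class StructureModel:
    """Guide tree (post-order node arrays) + emission/transition log-odds."""

    name: str
    length: int
    cutoff: float
    ntype: np.ndarray  # END/PAIR/LEFT/BIF per node, post-order (root last)
    child1: np.ndarray
    child2: np.ndarray
    pair_lo: np.ndarray  # nodes x 16, bits (PAIR nodes)
    single_lo: np.ndarray  # nodes x 4, bits (LEFT nodes)
    del_cost: np.ndarray  # bits, per node
    gap_open: float
    gap_extend: float
    null_model: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    @property
    def n_nodes(self) -> int:
        return self.ntype.size

    def node_counts(self) -> dict[str, int]:
        names = {END: "end", PAIR: "pair", LEFT: "left", BIF: "bifurcation"}
        return {
            v: int(np.sum(self.ntype == k)) for k, v in names.items()
        }

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "length": self.length,
                "cutoff": self.cutoff,
                "gap_open": self.gap_open,
                "gap_extend": self.gap_extend,
                "ntype": self.ntype.tolist(),
                "child1": self.child1.tolist(),
                "child2": self.child2.tolist(),
                "pair_lo": self.pair_lo.tolist(),
                "single_lo": self.single_lo.tolist(),
                "del_cost": self.del_cost.tolist(),
                "null_model": self.null_model.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StructureModel":
        d = json.loads(text)
        return cls(
            d["name"],
            d["length"],
            d["cutoff"],
            np.asarray(d["ntype"], dtype=np.int64),
            np.asarray(d["child1"], dtype=np.int64),
            np.asarray(d["child2"], dtype=np.int64),
            np.asarray(d["pair_lo"], dtype=np.float64),
            np.asarray(d["single_lo"], dtype=np.float64),
            np.asarray(d["del_cost"], dtype=np.float64),
            d["gap_open"],
            d["gap_extend"],
            np.asarray(d["null_model"], dtype=np.float64),
        )


def build_model(
    ex: StructureExemplar,
    pair_bonus: float = 0.0,
    mismatch_penalty: float = 0.0,
    gap_open: float = -4.0,
    gap_extend: float = -2.0,
    pseudocount: float = 0.05,
) -> StructureModel:
    """Build a covariance model from one exemplar.

    Emissions: pseudocount-smoothed log2-odds against a uniform null,
    maximized at the exemplar base (LEFT) / base pair (PAIR); ``pair_bonus``
    adds to the exemplar pair entry and ``mismatch_penalty`` subtracts from
    every non-exemplar entry (both default 0; the pseudocount already
    separates match from mismatch).  Deleting a node costs
    gap_open + gap_extend per base the node would emit.
    """
    if pseudocount <= 0 or pseudocount >= 1:
        raise ValueError("pseudocount must be in (0, 1)")
    match = _match_map(ex.structure)
    codes = encode_rna(ex.sequence)
    if (codes > 3).any():
        raise ValueError(f"{ex.name}: exemplar sequence contains ambiguous bases")

    ntype, child1, child2, emit_i, emit_j = [], [], [], [], []

    def add(t, c1=-1, c2=-1, ei=-1, ej=-1):
        ntype.append(t)
        child1.append(c1)
        child2.append(c2)
        emit_i.append(ei)
        emit_j.append(ej)
        return len(ntype) - 1

    def build(i, j):  # post-order: children appended before parents
        if i == j:
            return add(END)
        ch = ex.structure[i]
        if ch == ".":
            c = build(i + 1, j)
            return add(LEFT, c, ei=i)
        if ch == "(":
            k = match[i]
            if k == j - 1:
                c = build(i + 1, j - 1)
                return add(PAIR, c, ei=i, ej=k)
            c1 = build(i, k + 1)
            c2 = build(k + 1, j)
            return add(BIF, c1, c2)
        raise ValueError(f"unexpected ')' at position {i}")

    build(0, len(ex.sequence))

    n = len(ntype)
    pair_lo = np.zeros((n, 16))
    single_lo = np.zeros((n, 4))
    del_cost = np.zeros(n)
    a = pseudocount
    lo_pair_hit = np.log2(((1 + a) / (1 + 16 * a)) * 16) + pair_bonus
    lo_pair_miss = np.log2((a / (1 + 16 * a)) * 16) - mismatch_penalty
    lo_single_hit = np.log2(((1 + a) / (1 + 4 * a)) * 4)
    lo_single_miss = np.log2((a / (1 + 4 * a)) * 4) - mismatch_penalty
    for node in range(n):
        t = ntype[node]
        if t == PAIR:
            pair_lo[node, :] = lo_pair_miss
            pair_lo[node, 4 * codes[emit_i[node]] + codes[emit_j[node]]] = lo_pair_hit
            del_cost[node] = gap_open + 2 * gap_extend
        elif t == LEFT:
            single_lo[node, :] = lo_single_miss
            single_lo[node, codes[emit_i[node]]] = lo_single_hit
            del_cost[node] = gap_open + gap_extend
    return StructureModel(
        ex.name,
        len(ex.sequence),
        ex.cutoff,
        np.asarray(ntype, dtype=np.int64),
        np.asarray(child1, dtype=np.int64),
        np.asarray(child2, dtype=np.int64),
        pair_lo,
        single_lo,
        del_cost,
        gap_open,
        gap_extend,
    )


@njit(cache=True)
def _cyk(ntype, child1, child2, pair_lo, single_lo, del_cost, go, ge, codes):
    L = codes.size
    n = ntype.size
    T = np.full((n, L + 1, L + 1), NEG)
    R = np.empty((L + 1, L + 1))
    IL = np.empty((L + 1, L + 1))
    IR = np.empty((L + 1, L + 1))
    A = np.empty((L + 1, L + 1))
    for node in range(n):
        t = ntype[node]
        if t == 0:  # END: only insertions remain
            for i in range(L + 1):
                for j in range(i, L + 1):
                    sp = j - i
                    T[node, i, j] = 0.0 if sp == 0 else go + ge * sp
        elif t == 3:  # BIF
            c1 = child1[node]
            c2 = child2[node]
            for sp in range(L + 1):
                for i in range(L - sp + 1):
                    j = i + sp
                    best = NEG
                    for k in range(i, j + 1):
                        v = T[c1, i, k] + T[c2, k, j]
                        if v > best:
                            best = v
                    T[node, i, j] = best
        else:  # PAIR or LEFT with affine insert sweeps
            c = child1[node]
            for sp in range(L + 1):
                for i in range(L - sp + 1):
                    j = i + sp
                    best = del_cost[node] + T[c, i, j]
                    if t == 1 and sp >= 2:
                        ca = codes[i]
                        cb = codes[j - 1]
                        e = pair_lo[node, 4 * ca + cb] if (ca < 4 and cb < 4) else 0.0
                        v = e + T[c, i + 1, j - 1]
                        if v > best:
                            best = v
                    elif t == 2 and sp >= 1:
                        ca = codes[i]
                        e = single_lo[node, ca] if ca < 4 else 0.0
                        v = e + T[c, i + 1, j]
                        if v > best:
                            best = v
                    R[i, j] = best
                    if sp >= 1:
                        il = R[i + 1, j] + go + ge
                        v = IL[i + 1, j] + ge
                        if v > il:
                            il = v
                    else:
                        il = NEG
                    IL[i, j] = il
                    av = best if best > il else il
                    A[i, j] = av
                    if sp >= 1:
                        ir = A[i, j - 1] + go + ge
                        v = IR[i, j - 1] + ge
                        if v > ir:
                            ir = v
                    else:
                        ir = NEG
                    IR[i, j] = ir
                    T[node, i, j] = av if av > ir else ir
    return T[n - 1]


def score_window(m: StructureModel, seq: str) -> float:
    """Best bitscore of any alignment of the window to the model.

    End insertions at the root are free (glocal alignment): flanking
    sequence outside the matched region carries no penalty.  T and U, and
    upper/lower case, are equivalent; an empty window scores the all-delete
    path.
    """
    codes = encode_rna(seq).astype(np.int64)
    root = _cyk(
        m.ntype, m.child1, m.child2, m.pair_lo, m.single_lo, m.del_cost,
        m.gap_open, m.gap_extend, codes,
    )
    iu = np.triu_indices(root.shape[0])
    return float(root[iu].max())


def self_score(m: StructureModel, ex: StructureExemplar) -> float:
    return score_window(m, ex.sequence)


def scan_structures(
    m: StructureModel,
    seqs: dict,
    window: int = 250,
    slide: int = 75,
    cutoff: float | None = None,
) -> list[StructureHit]:
    """Tile each UTR, score every window, keep the per-gene best.

    The effective tile length is min(window, 2 x model length); sequences
    shorter than half the model length yield no windows and no hit.
    """
    if cutoff is None:
        cutoff = m.cutoff
    eff = min(window, 2 * m.length)
    min_len = int(np.ceil(0.5 * m.length))
    hits = []
    for gene, seq in seqs.items():
        L = len(seq)
        if L < min_len:
            continue
        starts = list(range(0, max(L - eff, 0) + 1, slide))
        if starts[-1] != max(L - eff, 0):
            starts.append(max(L - eff, 0))
        best = None
        for s in starts:
            sc = score_window(m, seq[s : s + eff])
            if best is None or sc > best[0]:
                best = (sc, s, min(s + eff, L))
        sc, s, e = best
        hits.append(StructureHit(gene, m.name, s, e, sc, sc >= cutoff))
    return hits


def hits_to_table(hits) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.gene_id, h.model, h.start, h.end, h.bitscore, h.passes) for h in hits],
        columns=["gene_id", "model", "start", "end", "bitscore", "passes"],
    )


def dinucleotide_shuffle(seq: str, rng=None, max_tries: int = 1000) -> str:
    """Altschul-Erikson dinucleotide-preserving shuffle.

    Preserves the exact dinucleotide counts (and hence mononucleotide
    composition) of the input.  Deterministic for a fixed ``rng`` seed.
    """
    rng = np.random.default_rng(rng)
    s = list(seq)
    n = len(s)
    if n <= 3:
        return seq
    first, last = s[0], s[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    verts = set(edges) | {last}
    for _ in range(max_tries):
        # pick a candidate terminal edge for every vertex except `last`
        last_edge = {}
        for v in edges:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        # the terminal edges must form paths leading into `last`
        ok = True
        for v in verts:
            if v == last:
                continue
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - pathological composition
        return seq
    out_lists = {}
    for v, lst in edges.items():
        rest = list(lst)
        if v in last_edge:
            rest.remove(last_edge[v])
        perm = [rest[i] for i in rng.permutation(len(rest))]
        if v in last_edge:
            perm.append(last_edge[v])
        out_lists[v] = perm
    walk = [first]
    ptr = {v: 0 for v in out_lists}
    cur = first
    for _ in range(n - 1):
        nxt = out_lists[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)
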