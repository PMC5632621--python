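"""Mk-model likelihood and marginal ancestral state reconstruction.

The one-parameter Markov k-state (Mk1) model assigns every ordered state
pair the same instantaneous rate alpha and a uniform stationary
distribution.  Its transition probability along a branch of length t has
the closed form

    P_ii(t) = 1/k + (k-1)/k * exp(-k*alpha*t)
    P_ij(t) = 1/k -     1/k * exp(-k*alpha*t)   (i != j)

Likelihoods are computed by Felsenstein's pruning algorithm with a
uniform 1/k root prior; the single rate is estimated by bounded
maximization, and per-node marginal state probabilities come from
combining each node's downward (subtree) partial likelihoods with the
complementary rest-of-tree partials, which is equivalent to re-rooting
at every node under this time-reversible model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

RATE_BOUNDS = (1e-8, 1e3)

HAIRPOINT_STATES = ("absent", "erect", "reflexed")
MISSING_TOKENS = {"", "?", "-", "na", "nan", "none", "missing"}


@dataclass
class ASRResult:
    """Marginal reconstruction for one character on one tree."""

    states: list
    node_probs: pd.DataFrame  # index: node label, columns: states, plus is_tip
    ml_rate: float
    log_likelihood: float
    rate_at_bound: bool = False


def mk1_transition(alpha: float, t: float, k: int) -> np.ndarray:
    """Mk1 transition probability matrix over a branch of length t."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if alpha < 0 or t < 0:
        raise ValueError("alpha and t must be nonnegative")
    decay = np.exp(-k * alpha * t)
    off = (1.0 - decay) / k
    P = np.full((k, k), off)
    np.fill_diagonal(P, 1.0 / k + (k - 1) / k * decay)
    return P


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; missing branch lengths are set to 1."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", rooting="default-rooted",
                             preserve_underscores=True)
    ensure_branch_lengths(tree)
    return tree


def ensure_branch_lengths(tree: dendropy.Tree) -> None:
    missing = [e for e in tree.preorder_edge_iter()
               if e.head_node.parent_node is not None and e.length is None]
    if missing:
        logger.warning("tree lacks %d branch lengths; set to 1.0", len(missing))
        for e in missing:
            e.length = 1.0


class _TreeArrays:
    """Postorder index arrays for fast repeated pruning on one tree."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes = list(tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children: list[list[int]] = []
        self.blen: list[float] = []
        self.is_tip: list[bool] = []
        self.labels: list[str] = []
        n_internal = 0
        for n in self.nodes:
            kids = n.child_nodes()
            self.children.append([index[id(c)] for c in kids])
            self.is_tip.append(not kids)
            if n.parent_node is None:
                self.blen.append(0.0)
            else:
                self.blen.append(float(n.edge.length) if n.edge.length is not None else 1.0)
            if not kids:
                self.labels.append(n.taxon.label if n.taxon else (n.label or f"tip{index[id(n)]}"))
            else:
                self.labels.append(n.label or f"node{n_internal}")
                n_internal += 1
        self.root = len(self.nodes) - 1
        self.parent = np.full(len(self.nodes), -1, dtype=int)
        for i, kids in enumerate(self.children):
            for c in kids:
                self.parent[c] = i


def _tip_partial(state, k: int, n_chars: int = 1) -> np.ndarray:
    out = np.ones((k, n_chars))
    if state is None:
        return out
    states = np.atleast_1d(state)
    for j, s in enumerate(states):
        if s is None or (isinstance(s, float) and np.isnan(s)) or s < 0:
            continue
        out[:, j] = 0.0
        out[int(s), j] = 1.0
    return out


def _down_partials(arrays: _TreeArrays, tip_states: dict, alpha: float, k: int,
                   n_chars: int = 1):
    """Scaled downward partial likelihoods, per node (k, n_chars).

    Returns (partials, log scale factor per character, transition matrices).
    """
    n = len(arrays.nodes)
    partials = [None] * n
    logscale = np.zeros(n_chars)
    Ps = [mk1_transition(alpha, t, k) for t in arrays.blen]
    for i in range(n):
        if arrays.is_tip[i]:
            lab = arrays.labels[i]
            if lab not in tip_states:
                raise KeyError(f"tip {lab!r} absent from character matrix")
            partials[i] = _tip_partial(tip_states[lab], k, n_chars)
        else:
            part = np.ones((k, n_chars))
            for c in arrays.children[i]:
                part = part * (Ps[c] @ partials[c])
            m = part.max(axis=0)
            safe = np.where(m > 0, m, 1.0)
            partials[i] = part / safe
            logscale += np.where(m > 0, np.log(safe), -np.inf)
    return partials, logscale, Ps


def mk1_loglik(tree: dendropy.Tree | _TreeArrays, tip_states: dict, alpha: float,
               k: int) -> float | np.ndarray:
    """Log-likelihood of tip states under Mk1 (uniform 1/k root prior).

    ``tip_states`` maps tip label -> state index (0..k-1), None/NaN for
    missing, or a sequence of state indices for several characters (then
    a vector of per-character log-likelihoods is returned).
    """
    arrays = tree if isinstance(tree, _TreeArrays) else _TreeArrays(tree)
    n_chars = _n_chars(tip_states)
    partials, logscale, _ = _down_partials(arrays, tip_states, alpha, k, n_chars)
    root_like = partials[arrays.root].sum(axis=0) / k
    with np.errstate(divide="ignore"):
        ll = np.log(root_like) + logscale
    return float(ll[0]) if n_chars == 1 and np.ndim(ll) else ll


def _n_chars(tip_states: dict) -> int:
    for v in tip_states.values():
        if v is not None and not np.isscalar(v) and not isinstance(v, float):
            return len(np.atleast_1d(v))
    return 1


def optimize_rate(tree: dendropy.Tree | _TreeArrays, tip_states: dict, k: int,
                  bounds: tuple[float, float] = RATE_BOUNDS) -> tuple[float, float, bool]:
    """ML estimate of the single Mk1 rate by bounded log-scale search.

    Returns (ml_rate, log_likelihood, at_bound).  An invariant character
    drives the estimate to the lower bound, which is flagged.
    """
    arrays = tree if isinstance(tree, _TreeArrays) else _TreeArrays(tree)
    observed = [v for v in tip_states.values()
                if v is not None and not (isinstance(v, float) and np.isnan(v))]
    if len(observed) < 2:
        raise ValueError("need >= 2 non-missing tips to estimate a rate")

    def neg_ll(log_alpha: float) -> float:
        return -float(np.sum(mk1_loglik(arrays, tip_states, 10.0 ** log_alpha, k)))

    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    ml_rate = float(10.0 ** res.x)
    at_bound = res.x - lo < 1e-4 or hi - res.x < 1e-4
    if at_bound:
        logger.info("optimize_rate: estimate pinned to bound (alpha=%.3g)", ml_rate)
    return ml_rate, float(-res.fun), at_bound


def marginal_asr(tree: dendropy.Tree | _TreeArrays, tip_states: dict, alpha: float,
                 k: int, states: list | None = None) -> ASRResult:
    """Marginal posterior state probabilities at every node.

    Downward partials are combined with the complementary rest-of-tree
    partials (uniform prior at the root), so each node's vector equals
    the brute-force conditional over all ancestral assignments.
    """
    arrays = tree if isinstance(tree, _TreeArrays) else _TreeArrays(tree)
    partials, _, Ps = _down_partials(arrays, tip_states, alpha, k, 1)
    n = len(arrays.nodes)
    up = [None] * n
    up[arrays.root] = np.full((k, 1), 1.0 / k)
    # preorder = reversed postorder
    for i in range(n - 1, -1, -1):
        kids = arrays.children[i]
        if not kids:
            continue
        down_through = [Ps[c] @ partials[c] for c in kids]
        for idx, c in enumerate(kids):
            rest = up[i].copy()
            for jdx, other in enumerate(down_through):
                if jdx != idx:
                    rest = rest * other
            up[c] = Ps[c].T @ rest
    probs = np.empty((n, k))
    for i in range(n):
        v = (partials[i] * up[i]).ravel()
        total = v.sum()
        if total <= 0:
            raise ValueError("zero likelihood: data impossible under the model")
        probs[i] = v / total
    state_names = list(states) if states is not None else list(range(k))
    df = pd.DataFrame(probs, index=arrays.labels, columns=[str(s) for s in state_names])
    df.insert(0, "is_tip", arrays.is_tip)
    ll = float(np.sum(mk1_loglik(arrays, tip_states, alpha, k)))
    return ASRResult(states=state_names, node_probs=df, ml_rate=alpha,
                     log_likelihood=ll, rate_at_bound=False)


def read_character_matrix(path: str | Path) -> pd.DataFrame:
    """Character matrix CSV: columns taxon, hairpoint, lamella_height."""
    df = pd.read_csv(path, dtype={"taxon": str})
    if "taxon" not in df.columns:
        raise ValueError(f"{path}: missing 'taxon' column")
    return df.set_index("taxon")


def _encode_column(column: pd.Series, state_map: dict | None = None):
    """Map raw character values to contiguous state indices.

    Returns (tip_states dict, ordered observed states).  The alphabet is
    the sorted set of observed (mapped) values; k is its size.
    """
    raw = {}
    for taxon, val in column.items():
        if pd.isna(val) or str(val).strip().lower() in MISSING_TOKENS:
            raw[str(taxon)] = None
            continue
        v = val
        if state_map is not None:
            v = state_map.get(val, state_map.get(str(val), val))
        raw[str(taxon)] = v
    observed = sorted({v for v in raw.values() if v is not None}, key=lambda x: (str(type(x)), x))
    index = {v: i for i, v in enumerate(observed)}
    return {t: (None if v is None else index[v]) for t, v in raw.items()}, observed


def asr_report(trees: dict[str, dendropy.Tree], matrix: pd.DataFrame,
               characters: list[str] | None = None,
               state_maps: dict[str, dict] | None = None) -> pd.DataFrame:
    """Marginal ASR tables for every tree x character combination.

    Each character's state alphabet is the set of values observed in the
    matrix (k = number of observed states); the rate is ML-optimized per
    tree and character.  Output rows carry the node label, tip flag,
    per-state probabilities, the ML rate and the log-likelihood.
    """
    characters = characters or [c for c in matrix.columns]
    out = []
    for tree_name, tree in trees.items():
        arrays = _TreeArrays(tree)
        tips = {lab for lab, is_tip in zip(arrays.labels, arrays.is_tip) if is_tip}
        missing = sorted(tips - set(matrix.index.astype(str)))
        if missing:
            raise ValueError(f"tree {tree_name!r}: tips absent from matrix: {missing}")
        for char in characters:
            smap = (state_maps or {}).get(char)
            tip_states, observed = _encode_column(matrix[char], smap)
            k = len(observed)
            if k < 2:
                logger.warning("character %s has <2 observed states; skipped", char)
                continue
            rate, ll, at_bound = optimize_rate(arrays, tip_states, k)
            asr = marginal_asr(arrays, tip_states, rate, k, states=observed)
            tbl = asr.node_probs.reset_index(names="node")
            tbl.insert(0, "character", char)
            tbl.insert(0, "tree", tree_name)
            tbl["ml_rate"] = rate
            tbl["log_likelihood"] = ll
            tbl["rate_at_bound"] = at_bound
            out.append(tbl)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)


def write_nexus_morph(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write the character matrix as a NEXUS standard-data block."""
    chars = list(matrix.columns)
    encoded = {}
    for c in chars:
        tip_states, observed = _encode_column(matrix[c])
        encoded[c] = (tip_states, observed)
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(matrix)} NCHAR={len(chars)};\n")
        fh.write('  FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS="0123456789";\n')
        fh.write("  MATRIX\n")
        for taxon in matrix.index:
            row = "".join(
                "?" if encoded[c][0][str(taxon)] is None else str(encoded[c][0][str(taxon)])
                for c in chars
            )
            fh.write(f"    {str(taxon).replace(' ', '_')} {row}\n")
        fh.write("  ;\nEND;\n")
        fh.write("[Characters: " + ", ".join(
            f"{c} states {encoded[c][1]}" for c in chars) + "]\n")
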