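"""Localized taxon quartet jackknife.

For a focal internal branch, each replicate draws one tip uniformly from each
of the four blocks of the branch's four-way partition, restricts the
alignment to those four rows, and infers the maximum-likelihood quartet
topology with an internal pruning-algorithm engine (JC69 by default, GTR
with fixed parameters optional). Any quartet topology either contains the
bipartition implied by the focal branch (index 0) or one of the two
conflicting resolutions (indices 1, 2); the per-branch tally of the three
outcomes over replicates feeds the ICA statistic.

Quartets with no usable character overlap cannot be resolved by data; they
are recorded with a uniformly random topology (flagged uninformative), which
is what a tree search forced to output a resolved quartet would effectively
do on contentless input.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .coverage_decisiveness import four_way_partition
from .trees_io import Alignment, Tree, ValidationError

__all__ = [
    "SubstitutionModel",
    "QuartetReplicate",
    "QuartetTally",
    "QuartetEngine",
    "sample_representative_quartet",
    "quartet_log_likelihood",
    "infer_quartet_topology",
    "quartet_jackknife_branch",
    "quartet_jackknife_tree",
]

BL_BOUNDS = (1e-8, 10.0)
LNL_TOL = 1e-6
TIE_TOL = 1e-9
_DATA_CHARS = b"ACGTRYSWKMBDHV"

# per-character conditional likelihood vectors over (A, C, G, T)
_CHAR_TABLE = np.ones((256, 4))
for _ch, _states in {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}.items():
    _vec = np.zeros(4)
    for _s in _states:
        _vec["ACGT".index(_s)] = 1.0
    _CHAR_TABLE[ord(_ch)] = _vec

_IS_DATA = np.zeros(256, dtype=bool)
for _b in _DATA_CHARS:
    _IS_DATA[_b] = True

# extended table for canonicalized codes: 0-3 are relabeled bases, 254 is
# "missing"; ASCII entries as in _CHAR_TABLE (bytes 0-3 never occur in data)
_PARTIAL_TABLE = _CHAR_TABLE.copy()
_PARTIAL_TABLE[0:4] = np.eye(4)
_PARTIAL_TABLE[254] = 1.0

_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
_IS_ACGT = _BASE_INDEX != 255


def _jc69_canonicalize(codes: np.ndarray) -> np.ndarray:
    """Collapse columns onto their base-permutation orbit for JC69.

    JC69 transition probabilities and root frequencies are invariant under
    any relabeling of the four bases, so a column's likelihood depends only
    on its partition pattern. Columns of pure ACGT/missing characters are
    rewritten with bases renamed 0,1,2,... in order of first appearance and
    missing as 254; columns containing partial ambiguity codes (whose state
    sets are not permutation-closed) are left as raw bytes.
    """
    is_missing = ~_IS_DATA[codes]
    ok = (_IS_ACGT[codes] | is_missing).all(axis=0)
    if not ok.any():
        return codes
    b = _BASE_INDEX[codes[:, ok]].astype(np.int16)
    b[is_missing[:, ok]] = -1
    m = b.shape[1]
    new = np.full((4, m), 254, dtype=np.uint8)
    assigned_label = np.full((4, m), -1, dtype=np.int16)
    next_label = np.zeros(m, dtype=np.int16)
    for r in range(4):
        v = b[r]
        has_data = v >= 0
        label = np.full(m, -1, dtype=np.int16)
        for r2 in range(r):
            match = has_data & (label < 0) & (b[r2] == v)
            label[match] = assigned_label[r2][match]
        fresh = has_data & (label < 0)
        label[fresh] = next_label[fresh]
        next_label[fresh] += 1
        assigned_label[r] = label
        new[r][has_data] = label[has_data].astype(np.uint8)
    out = codes.copy()
    out[:, ok] = new
    return out

#: tip pairings of the three quartet topologies in replicate tip order
#: (t1, t2, t3, t4): index 0 is the resolution consistent with the focal branch.
TOPOLOGY_PAIRS = ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2))


class SubstitutionModel:
    """JC69 (default) or GTR with fixed exchangeabilities and frequencies."""

    def __init__(self, name: str = "JC69", rates=None, freqs=None):
        name = name.upper()
        if name in ("JC", "JC69"):
            self.name = "JC69"
            self.freqs = np.full(4, 0.25)
            self._eig = None
        elif name == "GTR":
            self.name = "GTR"
            rates = np.asarray(rates, dtype=float)
            freqs = np.asarray(freqs, dtype=float)
            if rates.shape != (6,) or np.any(rates <= 0):
                raise ValidationError("GTR needs 6 positive exchangeabilities")
            if freqs.shape != (4,) or np.any(freqs <= 0):
                raise ValidationError("GTR needs 4 positive base frequencies")
            self.freqs = freqs / freqs.sum()
            self._eig = self._decompose(rates)
        else:
            raise ValidationError(f"unknown substitution model {name!r}")

    def _decompose(self, rates):
        q = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for r, (i, j) in zip(rates, idx):
            q[i, j] = r * self.freqs[j]
            q[j, i] = r * self.freqs[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.dot(self.freqs, np.diag(q))
        q /= scale  # one expected substitution per unit branch length
        # symmetrize with sqrt(pi): sym = diag(s) Q diag(1/s) is symmetric for
        # a reversible Q, so P(t) = diag(1/s) V exp(wt) V^T diag(s)
        s = np.sqrt(self.freqs)
        sym = (q * s[:, None]) / s[None, :]
        w, v = np.linalg.eigh((sym + sym.T) / 2)
        right = v / s[:, None]
        left = (v * s[:, None]).T
        return w, right, left

    def transition_matrix(self, t: float) -> np.ndarray:
        if self.name == "JC69":
            e = np.exp(-4.0 * t / 3.0)
            same = 0.25 + 0.75 * e
            diff = 0.25 - 0.25 * e
            p = np.full((4, 4), diff)
            np.fill_diagonal(p, same)
            return p
        w, right, left = self._eig
        p = (right * np.exp(w * t)) @ left
        return np.clip(p, 0.0, None)

    def propagate(self, partial: np.ndarray, t: float) -> np.ndarray:
        """partial @ P(t).T — conditional likelihoods pulled across a branch.
        JC69 avoids the matrix product: P = e*I + (1-e)/4 * ones."""
        if self.name == "JC69":
            e = math.exp(-4.0 * t / 3.0)
            return (0.25 - 0.25 * e) * partial.sum(axis=1, keepdims=True) + e * partial
        return partial @ self.transition_matrix(t).T


@dataclass(frozen=True)
class QuartetReplicate:
    branch: str
    tips: tuple
    topology: int  # 0 consistent with the focal branch, 1/2 conflicting
    lnls: tuple | None
    informative: bool
    tie: bool = False


@dataclass
class QuartetTally:
    """Counts of the three quartet resolutions over a branch's replicates."""

    branch: str
    counts: list  # [c_focal, c_alt1, c_alt2]
    n_uninformative: int = 0
    uninformative_counts: list | None = None
    replicates: list = field(default_factory=list)

    @property
    def n_reps(self) -> int:
        return int(sum(self.counts))

    def validate(self):
        if any(c < 0 for c in self.counts):
            raise ValidationError("negative tally counts")
        return self


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_representative_quartet(fwp, rng) -> tuple:
    """One tip drawn uniformly and independently from each of the four blocks
    (blocks iterated in sorted label order for reproducibility)."""
    tips = []
    for block in fwp.blocks:
        if not block:
            raise ValidationError("cannot sample a quartet from an empty block")
        ordered = sorted(block)
        tips.append(ordered[int(rng.integers(len(ordered)))])
    return tuple(tips)


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------


def _pattern_compress(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical columns of a (4, m) byte matrix into unique
    patterns with counts."""
    cols = np.ascontiguousarray(codes.T)
    packed = cols.view([("", cols.dtype)] * cols.shape[1]).ravel()
    _, first, counts = np.unique(packed, return_index=True, return_counts=True)
    return codes[:, np.sort(first)], counts[np.argsort(first)]


def _site_likelihoods(tip_partials, weights, pairing, model, bls):
    i, j, k, l = pairing
    u = model.propagate(tip_partials[i], bls[i]) * model.propagate(tip_partials[j], bls[j])
    v = model.propagate(tip_partials[k], bls[k]) * model.propagate(tip_partials[l], bls[l])
    site = (u * model.propagate(v, bls[4])) @ model.freqs
    return site, weights


def quartet_log_likelihood(
    topology: int,
    quartet_columns: np.ndarray,
    model: SubstitutionModel,
    branch_lengths,
    weights=None,
) -> float:
    """Pruning-algorithm log-likelihood of one quartet topology.

    `quartet_columns` is a (4, m) byte matrix (rows in replicate tip order);
    `branch_lengths` holds the four pendant lengths (tip order) then the
    internal length. Missing characters contribute all-ones conditional
    likelihood vectors.
    """
    codes = np.asarray(quartet_columns, dtype=np.uint8)
    if codes.ndim != 2 or codes.shape[0] != 4 or codes.shape[1] == 0:
        raise ValidationError("quartet likelihood needs a (4, m>=1) matrix")
    bls = np.asarray(branch_lengths, dtype=float)
    if bls.shape != (5,) or np.any(bls <= 0):
        raise ValidationError("need 5 positive branch lengths")
    if weights is None:
        weights = np.ones(codes.shape[1])
    tip_partials = [_CHAR_TABLE[codes[r]] for r in range(4)]
    site, w = _site_likelihoods(tip_partials, weights, TOPOLOGY_PAIRS[topology], model, bls)
    return float(np.dot(w, np.log(site)))


_E_LO = math.exp(-4.0 * BL_BOUNDS[1] / 3.0)
_E_HI = math.exp(-4.0 * BL_BOUNDS[0] / 3.0)


def _maximize_linear_in_e(alpha, beta, weights):
    """Maximize sum_i w_i log(alpha_i + beta_i e) over e in [_E_LO, _E_HI].

    The objective is strictly concave in e (second derivative < 0), so the
    optimum is at a boundary or at the unique root of the first derivative,
    found by Newton steps safeguarded with bisection.
    """

    def deriv(e):
        return float(np.dot(weights, beta / (alpha + beta * e)))

    if deriv(_E_HI) >= 0.0:
        return _E_HI
    if deriv(_E_LO) <= 0.0:
        return _E_LO
    lo, hi = _E_LO, _E_HI
    e = 0.5 * (lo + hi)
    for _ in range(60):
        ratio = beta / (alpha + beta * e)
        g1 = float(np.dot(weights, ratio))
        if g1 > 0.0:
            lo = e
        else:
            hi = e
        g2 = -float(np.dot(weights, ratio * ratio))
        e_new = e - g1 / g2 if g2 < 0.0 else 0.5 * (lo + hi)
        if not (lo < e_new < hi):
            e_new = 0.5 * (lo + hi)
        if abs(e_new - e) < 1e-13:
            return e_new
        e = e_new
    return e


def _jc69_optimize_topology(tip_partials, weights, pairing, model, max_cycles=20):
    """JC69 coordinate ascent where each one-branch subproblem is solved
    exactly: with e = exp(-4t/3), the per-site likelihood is linear in e, so
    the step reduces to a 1-D concave maximization (see above)."""
    tp = [tip_partials[x] for x in pairing]  # cherry order (u1, u2, v1, v2)
    base = [0.25 * t.sum(axis=1, keepdims=True) for t in tp]
    delta = [t - b for t, b in zip(tp, base)]
    freqs = model.freqs
    bls = np.full(5, 0.1)
    cond = [model.propagate(tp[x], bls[x]) for x in range(4)]

    def full_lnl():
        site = (cond[0] * cond[1] * model.propagate(cond[2] * cond[3], bls[4])) @ freqs
        return float(np.dot(weights, np.log(site)))

    current = full_lnl()
    for cycle in range(max_cycles):
        for b in range(5):
            if b < 2:
                fixed = cond[1 - b] * model.propagate(cond[2] * cond[3], bls[4])
                alpha = (base[b] * fixed) @ freqs
                beta = (delta[b] * fixed) @ freqs
            elif b < 4:
                u = cond[0] * cond[1]
                other = cond[5 - b]
                alpha = (u * model.propagate(base[b] * other, bls[4])) @ freqs
                beta = (u * model.propagate(delta[b] * other, bls[4])) @ freqs
            else:
                u = cond[0] * cond[1]
                v = cond[2] * cond[3]
                vbase = 0.25 * v.sum(axis=1, keepdims=True)
                alpha = (u * vbase) @ freqs
                beta = (u * (v - vbase)) @ freqs
            e = _maximize_linear_in_e(alpha, beta, weights)
            bls[b] = min(max(-0.75 * math.log(e), BL_BOUNDS[0]), BL_BOUNDS[1])
            if b < 4:
                cond[b] = model.propagate(tp[b], bls[b])
        new = full_lnl()
        if cycle >= 1 and new - current < LNL_TOL:
            current = max(new, current)
            break
        current = new
    return current, bls


def _optimize_topology(tip_partials, weights, pairing, model, max_cycles=20):
    """Cyclic bounded scalar optimization of the five branch lengths; at
    least two full cycles, stop when the lnL gain drops below LNL_TOL.

    Within each one-branch step the partial likelihoods that do not depend on
    the branch being optimized are held fixed, so a function evaluation costs
    one branch propagation plus elementwise products. JC69 dispatches to an
    exact coordinate solver.
    """
    if model.name == "JC69":
        return _jc69_optimize_topology(tip_partials, weights, pairing, model, max_cycles)
    tp = [tip_partials[x] for x in pairing]  # cherry order: (u1, u2, v1, v2)
    bls = np.full(5, 0.1)  # cherry order pendants + internal
    cond = [model.propagate(tp[x], bls[x]) for x in range(4)]
    freqs = model.freqs

    def full_lnl():
        u = cond[0] * cond[1]
        v = cond[2] * cond[3]
        site = (u * model.propagate(v, bls[4])) @ freqs
        return float(np.dot(weights, np.log(site)))

    current = full_lnl()
    opts = {"xatol": 1e-6, "maxiter": 60}
    for cycle in range(max_cycles):
        for b in range(5):
            if b < 2:  # pendant on the root-side cherry
                other = cond[1 - b]
                fixed = other * model.propagate(cond[2] * cond[3], bls[4])

                def neg(t, _tp=tp[b], _fixed=fixed):
                    site = (model.propagate(_tp, t) * _fixed) @ freqs
                    return -float(np.dot(weights, np.log(site)))

            elif b < 4:  # pendant on the far cherry
                other = cond[5 - b]
                u_fixed = cond[0] * cond[1]

                def neg(t, _tp=tp[b], _other=other, _u=u_fixed):
                    v = model.propagate(_tp, t) * _other
                    site = (_u * model.propagate(v, bls[4])) @ freqs
                    return -float(np.dot(weights, np.log(site)))

            else:  # internal branch
                u_fixed = cond[0] * cond[1]
                v_fixed = cond[2] * cond[3]

                def neg(t, _u=u_fixed, _v=v_fixed):
                    site = (_u * model.propagate(_v, t)) @ freqs
                    return -float(np.dot(weights, np.log(site)))

            res = minimize_scalar(neg, bounds=BL_BOUNDS, method="bounded", options=opts)
            bls[b] = float(res.x)
            if b < 4:
                cond[b] = model.propagate(tp[b], bls[b])
        new = full_lnl()
        if cycle >= 1 and new - current < LNL_TOL:
            current = max(new, current)
            break
        current = new
    return current, bls


class QuartetEngine:
    """Shared state for repeated quartet inference against one alignment:
    byte matrix, per-cell data mask, model, and a memo of per-quartet ML
    results keyed by the sorted tip set. RNG use is kept outside the memoized
    computation so results are identical with or without cache hits."""

    def __init__(self, alignment: Alignment, model: SubstitutionModel | None = None,
                 min_sites: int = 1):
        self.alignment = alignment
        self.model = model if model is not None else SubstitutionModel("JC69")
        self.min_sites = int(min_sites)
        self.codes = alignment.data
        self.is_data = _IS_DATA[self.codes]
        self._cache: dict[tuple, tuple] = {}

    def _ml_for_tipset(self, tips_sorted: tuple):
        """(informative, lnl_by_partner) for a sorted 4-tip set, where
        lnl_by_partner maps the tip paired with the smallest tip to the
        optimized lnL of that split."""
        hit = self._cache.get(tips_sorted)
        if hit is not None:
            return hit
        rows = np.array([self.alignment.row_index(t) for t in tips_sorted])
        mask = self.is_data[rows]
        colcount = mask.sum(axis=0)
        keep = colcount >= 2
        n3 = int((colcount >= 3).sum())
        if n3 < self.min_sites:
            result = (False, None)
        else:
            codes = self.codes[rows][:, keep]
            if self.model.name == "JC69":
                codes = _jc69_canonicalize(codes)
            patterns, weights = _pattern_compress(codes)
            tip_partials = [_PARTIAL_TABLE[patterns[r]] for r in range(4)]
            lnl_by_partner = {}
            for pairing in TOPOLOGY_PAIRS:
                partner = tips_sorted[pairing[1]]
                lnl, _ = _optimize_topology(tip_partials, weights, pairing, self.model)
                lnl_by_partner[partner] = lnl
            result = (True, lnl_by_partner)
        self._cache[tips_sorted] = result
        return result

    def infer(self, tips: tuple, rng, branch: str = "") -> QuartetReplicate:
        for t in tips:
            self.alignment.row_index(t)  # raises for unknown tips
        informative, lnl_by_partner = self._ml_for_tipset(tuple(sorted(tips)))
        if not informative:
            topo = int(rng.integers(3))
            return QuartetReplicate(branch, tuple(tips), topo, None, False)
        smallest = min(tips)
        lnls = []
        for pairing in TOPOLOGY_PAIRS:
            # identify each split by the tip paired with the smallest tip
            pair = {tips[pairing[0]], tips[pairing[1]]}
            if smallest not in pair:
                pair = set(tips) - pair
            partner = next(iter(pair - {smallest}))
            lnls.append(lnl_by_partner[partner])
        lnls = np.array(lnls)
        best = lnls.max()
        tied = [i for i in range(3) if best - lnls[i] <= TIE_TOL]
        if len(tied) > 1:
            topo = tied[int(rng.integers(len(tied)))]
            tie = True
        else:
            topo = tied[0]
            tie = False
        return QuartetReplicate(branch, tuple(tips), topo, tuple(map(float, lnls)), True, tie)


def infer_quartet_topology(
    tips,
    alignment: Alignment,
    model: SubstitutionModel | None = None,
    rng=None,
    min_sites: int = 1,
    engine: QuartetEngine | None = None,
) -> QuartetReplicate:
    """ML topology for one quartet of tips against the full alignment.

    Columns where fewer than 2 of the 4 taxa have data are dropped; if fewer
    than `min_sites` retained columns have data for >= 3 taxa the replicate is
    uninformative and resolved uniformly at random. Exact lnL ties are broken
    uniformly among the tied topologies.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if engine is None:
        engine = QuartetEngine(alignment, model, min_sites)
    return engine.infer(tuple(tips), rng)


# ---------------------------------------------------------------------------
# jackknife over branches
# ---------------------------------------------------------------------------


def _branch_seed(seed: int, key: str) -> int:
    digest = hashlib.sha256(f"{seed}:{key}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def quartet_jackknife_branch(
    tree: Tree,
    edge,
    alignment: Alignment,
    n_reps: int = 500,
    model: SubstitutionModel | None = None,
    rng=None,
    min_sites: int = 1,
    engine: QuartetEngine | None = None,
    keep_replicates: bool = True,
    resample_uninformative: int = 0,
) -> QuartetTally:
    """Tally of quartet resolutions for one internal branch over `n_reps`
    replicates (drawn with replacement). With `resample_uninformative` = k,
    an uninformative draw is retried up to k times before being recorded
    with a random topology."""
    fwp = four_way_partition(tree, edge)
    missing = set(tree.tip_labels) - set(alignment.taxa)
    if missing:
        raise ValidationError(f"tips absent from alignment: {sorted(missing)}")
    if engine is None:
        engine = QuartetEngine(alignment, model, min_sites)
    if rng is None:
        rng = np.random.default_rng(0)
    counts = [0, 0, 0]
    uninf_counts = [0, 0, 0]
    n_uninf = 0
    replicates = []
    for _ in range(n_reps):
        tips = sample_representative_quartet(fwp, rng)
        rep = engine.infer(tips, rng, branch=fwp.edge_key)
        for _retry in range(resample_uninformative):
            if rep.informative:
                break
            tips = sample_representative_quartet(fwp, rng)
            rep = engine.infer(tips, rng, branch=fwp.edge_key)
        counts[rep.topology] += 1
        if not rep.informative:
            n_uninf += 1
            uninf_counts[rep.topology] += 1
        if keep_replicates:
            replicates.append(rep)
    return QuartetTally(
        branch=fwp.edge_key,
        counts=counts,
        n_uninformative=n_uninf,
        uninformative_counts=uninf_counts,
        replicates=replicates,
    ).validate()


def _run_branch(tree, edge_key, alignment, n_reps, model, seed, min_sites,
                keep_replicates):
    # re-resolve the edge from its key so the task is picklable
    edges = {tree.edge_key(e): e for e in tree.internal_edges()}
    engine = QuartetEngine(alignment, model, min_sites)
    rng = np.random.default_rng(_branch_seed(seed, edge_key))
    return quartet_jackknife_branch(
        tree, edges[edge_key], alignment, n_reps=n_reps, model=model, rng=rng,
        min_sites=min_sites, engine=engine, keep_replicates=keep_replicates,
    )


def quartet_jackknife_tree(
    tree: Tree,
    alignment: Alignment,
    n_reps: int = 500,
    model: SubstitutionModel | None = None,
    seed: int = 0,
    workers: int = 1,
    min_sites: int = 1,
    keep_replicates: bool = False,
) -> dict[str, QuartetTally]:
    """Quartet-jackknife tallies for every internal branch of the unrooted
    view (terminal branches carry no meaningful support and are excluded).

    Each branch draws from its own RNG stream keyed by (seed, canonical
    bipartition), so results do not depend on traversal order or on the
    degree of parallelism.
    """
    edges = tree.internal_edges()
    keys = [tree.edge_key(e) for e in edges]
    if workers > 1:
        from joblib import Parallel, delayed

        tallies = Parallel(n_jobs=workers)(
            delayed(_run_branch)(
                tree, key, alignment, n_reps, model, seed, min_sites, keep_replicates
            )
            for key in keys
        )
        return dict(zip(keys, tallies))
    engine = QuartetEngine(alignment, model, min_sites)
    out = {}
    for key, edge in zip(keys, edges):
        rng = np.random.default_rng(_branch_seed(seed, key))
        out[key] = quartet_jackknife_branch(
            tree, edge, alignment, n_reps=n_reps, model=model, rng=rng,
            min_sites=min_sites, engine=engine, keep_replicates=keep_replicates,
        )
    return out
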