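"""Phylogenetic comparative methods for fruit-type evolution.

Discrete fruit type (AC = 0, ER = 1) evolves under a two-state Markov (Mk)
model with forward rate ``q01`` (AC -> ER) and backward rate ``q10`` per
unit branch length.  The module provides the pruning-algorithm likelihood,
maximum-likelihood rate fitting, marginal ancestral-state reconstruction,
transition counting, Blomberg's K phylogenetic signal with a permutation
test, Brownian-motion ancestral states for continuous (log) morphometrics,
and a joint tree/trait simulator used as ground truth in tests.

Trees are rooted, branch-length-bearing dendropy trees behind a thin
:class:`Phylogeny` wrapper.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np


class PhyloError(ValueError):
    pass


STATE_CODES = {"AC": 0, "ER": 1, 0: 0, 1: 1, 0.0: 0, 1.0: 1}
STATE_NAMES = ("AC", "ER")


# ---------------------------------------------------------------------------
# tree container

class Phylogeny:
    """Rooted tree with unique tip labels and branch lengths.

    Internal nodes receive stable labels (``nd<i>`` in preorder) if unlabeled.
    Zero or missing branch lengths can be replaced by a small epsilon (a
    fraction of tree height) for algorithms that require positive lengths.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise PhyloError("duplicate tip labels")
        i = 0
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            if nd.label is None:
                nd.label = f"nd{i}"
            i += 1
        self._index()

    def _index(self) -> None:
        self.postorder = list(self.tree.postorder_node_iter())
        self.node_index = {id(nd): k for k, nd in enumerate(self.postorder)}
        self.tip_labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def fully_bifurcating(self) -> bool:
        return all(
            nd.num_child_nodes() == 2
            for nd in self.tree.preorder_internal_node_iter()
        )

    def height(self) -> float:
        best = 0.0
        for lf in self.tree.leaf_node_iter():
            d, nd = 0.0, lf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            best = max(best, d)
        return best

    def ensure_positive_lengths(self, epsilon_frac: float = 1e-6) -> list[str]:
        """Replace zero/missing branch lengths by ``epsilon_frac * height``."""
        eps = max(self.height(), 1.0) * epsilon_frac
        warnings = []
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            if not nd.edge.length or nd.edge.length <= 0:
                warnings.append(
                    f"branch above {nd.taxon.label if nd.is_leaf() else nd.label} "
                    f"set to epsilon {eps:g}")
                nd.edge.length = eps
        return warnings

    def vcv(self) -> tuple[np.ndarray, list[str]]:
        """Brownian covariance among tips: shared root-to-MRCA path lengths."""
        tips = list(self.tree.leaf_node_iter())
        labels = [t.taxon.label for t in tips]
        depth = {}
        for nd in self.tree.preorder_node_iter():
            p = nd.parent_node
            depth[id(nd)] = (depth[id(p)] if p is not None else 0.0) + (nd.edge.length or 0.0)
        anc = {}
        for k, t in enumerate(tips):
            nd = t
            while nd is not None:
                anc.setdefault(id(nd), []).append(k)
                nd = nd.parent_node
        n = len(tips)
        C = np.zeros((n, n))
        # shared path length of tips i, j = depth of their MRCA
        for nd in self.tree.postorder_node_iter():
            below = anc[id(nd)]
            if nd.is_leaf():
                C[below[0], below[0]] = depth[id(nd)]
                continue
            kids = nd.child_nodes()
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in anc[id(kids[a])]:
                        for j in anc[id(kids[b])]:
                            C[i, j] = C[j, i] = depth[id(nd)]
        return C, labels


def read_newick(source) -> Phylogeny:
    """Parse a Newick string or file path into a :class:`Phylogeny`."""
    text = str(source)
    if "\n" not in text and not text.strip().startswith("(") and not text.strip().endswith(";"):
        text = open(source).read()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise PhyloError(f"newick parse error: {exc}") from exc
    if not list(tree.leaf_node_iter()) or all(
        lf.taxon is None for lf in tree.leaf_node_iter()
    ):
        raise PhyloError("newick parse error: no labeled tips")
    return Phylogeny(tree)


def write_newick(phy: Phylogeny) -> str:
    return phy.tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True,
        real_value_format_specifier=".17g",
    ).strip()


# ---------------------------------------------------------------------------
# Mk model

@dataclass
class MkModel:
    """Two-state Markov model: forward rate AC->ER, backward rate ER->AC."""

    q01: float
    q10: float
    root_prior: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise PhyloError("Mk rates must be >= 0")
        s = sum(self.root_prior)
        if not math.isclose(s, 1.0, rel_tol=1e-9):
            raise PhyloError("root prior must sum to 1")

    @property
    def Q(self) -> np.ndarray:
        return np.array([[-self.q01, self.q01], [self.q10, -self.q10]])

    def transition_matrix(self, t: float) -> np.ndarray:
        """Closed-form matrix exponential of the 2-state rate matrix."""
        a, b = self.q01, self.q10
        s = a + b
        if s == 0.0:
            return np.eye(2)
        e = math.exp(-s * t)
        return np.array([
            [(b + a * e) / s, (a - a * e) / s],
            [(b - b * e) / s, (a + b * e) / s],
        ])

    def stationary(self) -> tuple[float, float]:
        s = self.q01 + self.q10
        if s == 0.0:
            return (0.5, 0.5)
        return (self.q10 / s, self.q01 / s)


def _coded_states(phy: Phylogeny, tip_states: dict) -> dict[str, int]:
    coded = {}
    for label in phy.tip_labels:
        if label not in tip_states:
            raise PhyloError(f"tip {label!r} has no state (missing data unsupported)")
        try:
            coded[label] = STATE_CODES[tip_states[label]]
        except KeyError:
            raise PhyloError(f"invalid state {tip_states[label]!r} for tip {label!r}")
    return coded


def _partials(phy: Phylogeny, coded: dict[str, int], model: MkModel) -> np.ndarray:
    """Postorder conditional likelihoods (Felsenstein pruning), one row per node."""
    L = np.zeros((len(phy.postorder), 2))
    for k, nd in enumerate(phy.postorder):
        if nd.is_leaf():
            L[k, coded[nd.taxon.label]] = 1.0
            continue
        row = np.ones(2)
        for ch in nd.child_nodes():
            P = model.transition_matrix(ch.edge.length or 0.0)
            row *= P @ L[phy.node_index[id(ch)]]
        L[k] = row
    return L


def mk_loglik(phy: Phylogeny, tip_states: dict, model: MkModel) -> float:
    """Log-likelihood of binary tip states under the Mk model (root prior applied)."""
    coded = _coded_states(phy, tip_states)
    L = _partials(phy, coded, model)
    lik = float(np.dot(model.root_prior, L[-1]))
    return math.log(lik) if lik > 0 else -math.inf


@dataclass
class MkFitResult:
    model: MkModel
    log_likelihood: float
    aic: float
    model_form: str
    degenerate: bool = False


def fit_mk(
    phy: Phylogeny, tip_states: dict, model_form: str = "ARD",
    root_prior: tuple[float, float] = (0.5, 0.5),
    bounds: tuple[float, float] = (1e-8, 1e3),
) -> MkFitResult:
    """Maximum-likelihood Mk rates.

    ``model_form`` is ``"ER"`` (equal rates, one parameter -- the usual Mk
    naming, unrelated to the ER fruit type) or ``"ARD"`` (all rates
    different, two parameters).  Monomorphic tip data drive the rates to the
    lower bound and are flagged degenerate.
    """
    from scipy import optimize

    if phy.n_tips < 4:
        raise PhyloError("need >= 4 tips to fit rates")
    coded = _coded_states(phy, tip_states)
    values = set(coded.values())
    k = 1 if model_form == "ER" else 2
    lo, hi = math.log(bounds[0]), math.log(bounds[1])

    if len(values) == 1:
        model = MkModel(bounds[0], bounds[0], root_prior)
        ll = mk_loglik(phy, tip_states, model)
        return MkFitResult(model, ll, 2 * k - 2 * ll, model_form, degenerate=True)

    def nll(logq):
        if model_form == "ER":
            m = MkModel(math.exp(logq[0]), math.exp(logq[0]), root_prior)
        else:
            m = MkModel(math.exp(logq[0]), math.exp(logq[1]), root_prior)
        ll = mk_loglik(phy, tip_states, m)
        # keep the objective finite where the data are impossible (rate -> 0)
        return -ll if math.isfinite(ll) else 1e12

    x0 = np.full(k, math.log(1.0 / max(phy.height(), 1e-9)))
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * k,
        options=dict(ftol=1e-14, gtol=1e-12),
    )
    q = np.exp(res.x)
    model = MkModel(q[0], q[0] if model_form == "ER" else q[1], root_prior)
    ll = -res.fun
    return MkFitResult(model, ll, 2 * k - 2 * ll, model_form)


# ---------------------------------------------------------------------------
# ancestral states

@dataclass
class ASRResult:
    kind: str  # "discrete" | "continuous"
    node_values: dict[str, object] = field(default_factory=dict)
    map_states: dict[str, str] = field(default_factory=dict)
    tip_states: dict[str, str] = field(default_factory=dict)


def marginal_asr(phy: Phylogeny, tip_states: dict, model: MkModel) -> ASRResult:
    """Marginal posterior state probabilities at every internal node.

    Uses the standard outside/inside decomposition, equivalent to re-rooting
    the tree at each node: the marginal at a node is the normalized product
    of the likelihood of the data below it and the likelihood flowing from
    the rest of the tree (with the root prior applied at the root).
    """
    if not phy.fully_bifurcating:
        bad = next(nd for nd in phy.tree.preorder_internal_node_iter()
                   if nd.num_child_nodes() != 2)
        raise PhyloError(f"tree not fully bifurcating at node {bad.label!r}")
    coded = _coded_states(phy, tip_states)
    L = _partials(phy, coded, model)
    prior = np.asarray(model.root_prior)

    # outside pass (preorder): G[v][s] = likelihood of all data outside the
    # clade of v, given the state at v's parent-facing end is s
    G = np.zeros_like(L)
    root = phy.postorder[-1]
    G[phy.node_index[id(root)]] = prior
    for nd in phy.tree.preorder_node_iter():
        gi = G[phy.node_index[id(nd)]]
        for ch in nd.child_nodes():
            sib_term = np.ones(2)
            for sib in nd.child_nodes():
                if sib is ch:
                    continue
                Ps = model.transition_matrix(sib.edge.length or 0.0)
                sib_term *= Ps @ L[phy.node_index[id(sib)]]
            Pc = model.transition_matrix(ch.edge.length or 0.0)
            G[phy.node_index[id(ch)]] = (gi * sib_term) @ Pc

    res = ASRResult(kind="discrete")
    for nd in phy.tree.preorder_node_iter():
        k = phy.node_index[id(nd)]
        post = G[k] * L[k]
        tot = post.sum()
        if tot <= 0:
            raise PhyloError("zero likelihood: tip data impossible under model")
        post = post / tot
        if nd.is_leaf():
            res.tip_states[nd.taxon.label] = STATE_NAMES[coded[nd.taxon.label]]
        else:
            res.node_values[nd.label] = post
            res.map_states[nd.label] = STATE_NAMES[int(np.argmax(post))]
    return res


def count_transitions(
    phy: Phylogeny, asr: ASRResult, tip_states: dict,
    method: str = "map", model: MkModel | None = None,
    n_maps: int = 100, seed: int | None = None,
) -> dict:
    """Count fruit-type transitions along edges.

    ``method="map"`` compares maximum-a-posteriori states of parent and
    child (tips use observed states) and returns integer counts of forward
    (AC -> ER) and reverse (ER -> AC) changes.  ``method="stochastic"``
    samples joint node states from their conditional distribution
    (backward-filtering / forward-sampling, seeded) and returns the mean
    counts over ``n_maps`` draws as a sensitivity check.
    """
    coded = _coded_states(phy, tip_states)

    def state_of(nd, states):
        if nd.is_leaf():
            return coded[nd.taxon.label]
        return states[nd.label]

    if method == "map":
        states = {lbl: STATE_CODES[s] for lbl, s in asr.map_states.items()}
        fwd = rev = 0
        for nd in phy.tree.preorder_node_iter():
            for ch in nd.child_nodes():
                a, b = state_of(nd, states), state_of(ch, states)
                if a == 0 and b == 1:
                    fwd += 1
                elif a == 1 and b == 0:
                    rev += 1
        return {"AC->ER": fwd, "ER->AC": rev}

    if method != "stochastic":
        raise PhyloError(f"unknown transition-count method {method!r}")
    if model is None:
        raise PhyloError("stochastic mapping requires the Mk model")
    rng = np.random.default_rng(seed)
    L = _partials(phy, coded, model)
    prior = np.asarray(model.root_prior)
    fwd_tot = rev_tot = 0.0
    for _ in range(n_maps):
        sampled: dict[int, int] = {}
        root = phy.postorder[-1]
        w = prior * L[-1]
        sampled[id(root)] = int(rng.random() < w[1] / w.sum())
        fwd = rev = 0
        for nd in phy.tree.preorder_node_iter():
            a = sampled[id(nd)]
            for ch in nd.child_nodes():
                P = model.transition_matrix(ch.edge.length or 0.0)
                w = P[a] * L[phy.node_index[id(ch)]]
                b = int(rng.random() < w[1] / w.sum())
                sampled[id(ch)] = b
                fwd += a == 0 and b == 1
                rev += a == 1 and b == 0
        fwd_tot += fwd
        rev_tot += rev
    return {"AC->ER": fwd_tot / n_maps, "ER->AC": rev_tot / n_maps}


# ---------------------------------------------------------------------------
# phylogenetic signal

@dataclass
class PhyloSignalResult:
    K: float
    p_value: float | None
    n_perm: int
    seed: int | None


def _k_statistic(C: np.ndarray, x: np.ndarray) -> float:
    n = len(x)
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    denom = one @ Ci @ one
    a_hat = (one @ Ci @ x) / denom
    d = x - a_hat
    mse0 = (d @ d) / (n - 1)
    mse = (d @ Ci @ d) / (n - 1)
    expected = (np.trace(C) - n / denom) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(
    phy: Phylogeny, tip_values: dict, n_perm: int = 999, seed: int | None = None
) -> PhyloSignalResult:
    """Blomberg's K with a tip-shuffling permutation test.

    K compares the observed ratio of the non-phylogenetic to the
    phylogenetically corrected mean squared error (about the GLS
    phylogenetic mean) with its Brownian-motion expectation; K = 1 is the BM
    calibration, K < 1 means less resemblance among relatives than BM
    predicts.  Binary traits may be passed as 0/1 (or AC/ER) and are treated
    as continuous, an approximation.  The p-value is the fraction of label
    permutations whose MSE0/MSE ratio is at least the observed one.
    """
    C, labels = phy.vcv()
    off = C[~np.eye(len(labels), dtype=bool)]
    if len(labels) < 4 or np.all(off == 0):
        raise PhyloError("K undefined: tree has no shared internal structure")
    x = np.array([
        float(STATE_CODES.get(tip_values[l], tip_values[l])) if not isinstance(tip_values[l], float)
        else tip_values[l]
        for l in labels
    ])
    K_obs = _k_statistic(C, x)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        Ci = np.linalg.inv(C)
        one = np.ones(len(x))
        denom = one @ Ci @ one
        expected = (np.trace(C) - len(x) / denom) / (len(x) - 1)

        def ratio(v):
            a = (one @ Ci @ v) / denom
            d = v - a
            return (d @ d) / (d @ Ci @ d)

        obs = ratio(x)
        hits = sum(ratio(rng.permutation(x)) >= obs for _ in range(n_perm))
        p = (hits + 1) / (n_perm + 1)
    return PhyloSignalResult(K=float(K_obs), p_value=p, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# continuous ancestral states (Brownian motion)

def brownian_asr(phy: Phylogeny, tip_values: dict) -> ASRResult:
    """ML ancestral values under Brownian motion via GLS prediction.

    The root estimate is the GLS phylogenetic mean; every other internal
    node is the conditional expectation
    ``mu + c_a' C^-1 (x - mu)`` where ``c_a[i]`` is the shared path length
    between node ``a`` and tip ``i`` (the depth of their MRCA).  Equal to
    the re-rooted ML estimate used by standard comparative packages.
    """
    C, labels = phy.vcv()
    x = np.array([float(tip_values[l]) for l in labels])
    n = len(x)
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    mu = (one @ Ci @ x) / (one @ Ci @ one)

    depth = {}
    anc_tips: dict[int, set[int]] = {}
    tip_pos = {l: i for i, l in enumerate(labels)}
    for nd in phy.tree.preorder_node_iter():
        p = nd.parent_node
        depth[id(nd)] = (depth[id(p)] if p is not None else 0.0) + (nd.edge.length or 0.0)
    for nd in phy.tree.postorder_node_iter():
        if nd.is_leaf():
            anc_tips[id(nd)] = {tip_pos[nd.taxon.label]}
        else:
            s = set()
            for ch in nd.child_nodes():
                s |= anc_tips[id(ch)]
            anc_tips[id(nd)] = s

    res = ASRResult(kind="continuous")
    resid = Ci @ (x - mu)
    for nd in phy.tree.preorder_internal_node_iter():
        inside = anc_tips[id(nd)]
        d_a = depth[id(nd)]
        c = np.empty(n)
        for i in range(n):
            if i in inside:
                c[i] = d_a  # MRCA(a, tip below a) = a itself
            else:
                # MRCA is the deepest ancestor of a that also covers tip i
                anc = nd
                while i not in anc_tips[id(anc)]:
                    anc = anc.parent_node
                c[i] = depth[id(anc)]
        res.node_values[nd.label] = float(mu + c @ resid)
    for l in labels:
        res.tip_states[l] = float(tip_values[l])
    return res


def categorize_changes(
    phy: Phylogeny, asr: ASRResult, epsilon: float = 0.05
) -> dict[str, str]:
    """Per-tip change category relative to the reconstructed parent value.

    A tip whose value differs from its parent's estimate by at most
    ``epsilon`` times the trait range (tips plus reconstructed nodes) is
    "same"; otherwise "increase" or "decrease".
    """
    if epsilon < 0:
        raise PhyloError("epsilon must be >= 0")
    if asr.kind != "continuous":
        raise PhyloError("categorize_changes requires a continuous reconstruction")
    vals = list(asr.node_values.values()) + list(asr.tip_states.values())
    span = max(vals) - min(vals)
    thresh = epsilon * span
    out = {}
    for lf in phy.tree.leaf_node_iter():
        parent = lf.parent_node
        pv = asr.node_values[parent.label]
        delta = asr.tip_states[lf.taxon.label] - pv
        if abs(delta) <= thresh:
            out[lf.taxon.label] = "same"
        else:
            out[lf.taxon.label] = "increase" if delta > 0 else "decrease"
    return out


# ---------------------------------------------------------------------------
# simulation

@dataclass
class SimulatedStudyTraits:
    phylogeny: Phylogeny
    tip_states: dict[str, str]
    node_states: dict[str, str]
    true_changes: dict[str, int]  # realized jump counts: "AC->ER", "ER->AC"
    tip_values: dict[str, float]
    node_values: dict[str, float]


def simulate_birth_death(
    n_tips: int, birth: float, death: float, seed: int, max_retries: int = 50
) -> Phylogeny:
    """Birth-death tree conditioned on ``n_tips`` extant tips, seeded."""
    if n_tips < 2:
        raise PhyloError("need n_tips >= 2")
    if not (birth > death >= 0):
        raise PhyloError("need birth > death >= 0")
    from dendropy.simulate import treesim

    rng_py = random.Random(seed)
    tree = None
    for _ in range(max_retries):
        try:
            tree = treesim.birth_death_tree(
                birth_rate=birth, death_rate=death, num_extant_tips=n_tips,
                rng=rng_py,
            )
            break
        except Exception:
            continue
    if tree is None:
        raise PhyloError(f"birth-death simulation failed after {max_retries} attempts")
    for k, lf in enumerate(tree.leaf_node_iter()):
        lf.taxon.label = f"sp{k + 1:03d}"
    phy = Phylogeny(tree)
    # conditioning on tip count leaves the newest cherry with zero-length
    # terminal branches; nudge them so tip covariances stay nonsingular
    phy.ensure_positive_lengths()
    return phy


def rescale_height(phy: Phylogeny, height: float = 1.0) -> Phylogeny:
    """Scale all branch lengths so the maximum root-to-tip depth is ``height``."""
    h = phy.height()
    if h <= 0:
        raise PhyloError("cannot rescale a zero-height tree")
    f = height / h
    for nd in phy.tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= f
    return phy


def simulate_mk_history(phy: Phylogeny, mk: MkModel, rng: np.random.Generator):
    """Exact CTMC history on the tree: node states plus realized jump counts."""
    states: dict[int, int] = {}
    root = phy.postorder[-1]
    states[id(root)] = int(rng.random() < mk.root_prior[1])
    jumps = {"AC->ER": 0, "ER->AC": 0}
    rates = (mk.q01, mk.q10)
    for nd in phy.tree.preorder_node_iter():
        for ch in nd.child_nodes():
            s, remaining = states[id(nd)], ch.edge.length or 0.0
            while True:
                rate = rates[s]
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait >= remaining:
                    break
                remaining -= wait
                jumps["AC->ER" if s == 0 else "ER->AC"] += 1
                s = 1 - s
            states[id(ch)] = s
    return states, jumps


def simulate_bm(
    phy: Phylogeny, sigma: float, rng: np.random.Generator, root_value: float = 0.0
) -> dict[int, float]:
    """Brownian trait values at every node (variance ``sigma^2 t`` per branch)."""
    vals: dict[int, float] = {id(phy.postorder[-1]): root_value}
    for nd in phy.tree.preorder_node_iter():
        for ch in nd.child_nodes():
            t = ch.edge.length or 0.0
            vals[id(ch)] = vals[id(nd)] + rng.normal(0.0, sigma * math.sqrt(t))
    return vals


def simulate_tree_and_traits(
    n_tips: int,
    birth: float,
    death: float,
    mk: MkModel,
    bm_sigma: float,
    seed: int,
    bm_root: float = 0.0,
    max_retries: int = 50,
) -> SimulatedStudyTraits:
    """Birth-death tree conditioned on ``n_tips`` plus Mk and BM traits.

    The Mk history is simulated with exact exponential waiting times, so the
    realized number of forward/backward jumps (not just endpoint states) is
    recorded.  The BM trait accrues variance ``bm_sigma^2 * t`` along each
    branch.  Fully reproducible from ``seed``.
    """
    phy = simulate_birth_death(n_tips, birth, death, seed, max_retries)
    rng = np.random.default_rng(seed)
    node_states, jumps = simulate_mk_history(phy, mk, rng)
    node_bm = simulate_bm(phy, bm_sigma, rng, bm_root)

    tip_states, node_states_out, tip_values, node_values = {}, {}, {}, {}
    for nd in phy.tree.preorder_node_iter():
        if nd.is_leaf():
            tip_states[nd.taxon.label] = STATE_NAMES[node_states[id(nd)]]
            tip_values[nd.taxon.label] = node_bm[id(nd)]
        else:
            node_states_out[nd.label] = STATE_NAMES[node_states[id(nd)]]
            node_values[nd.label] = node_bm[id(nd)]
    return SimulatedStudyTraits(
        phylogeny=phy, tip_states=tip_states, node_states=node_states_out,
        true_changes=jumps, tip_values=tip_values, node_values=node_values,
    )
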