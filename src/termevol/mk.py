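"""Binary-trait Mk model: likelihood, rate estimation, stochastic mapping.

The default model is the 2-state equal-rates Mk process (for two states the
equal-rates and symmetric models coincide) with a uniform root prior; a
stationary prior is exposed as an option.  Ancestral states are summarized
by stochastic character mapping: node states are sampled from their joint
conditional distribution (Felsenstein pruning followed by a preorder
sampling pass), and explicit change histories along branches are drawn
conditional on the sampled endpoint states — by rejection sampling with a
bounded retry budget, falling back to exact uniformization when a branch's
endpoint combination is too improbable to hit by rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .tree import Phylogeny

__all__ = [
    "MkModel",
    "MkResults",
    "SimmapHistory",
    "mk_loglik",
    "fit_mk",
    "stochastic_map",
]


def _transition_matrix(q: float, t: float) -> np.ndarray:
    """P(t) for the 2-state equal-rates Mk process (analytic expm)."""
    same = 0.5 + 0.5 * np.exp(-2.0 * q * t)
    return np.array([[same, 1.0 - same], [1.0 - same, same]])


def _tip_state_array(tree: Phylogeny, tip_states) -> np.ndarray:
    if isinstance(tip_states, dict):
        try:
            states = [tip_states[l] for l in tree.tip_labels]
        except KeyError as err:
            raise ValueError(f"missing state for tip {err.args[0]!r}") from None
    else:
        states = list(tip_states)
        if len(states) != tree.n_tips:
            raise ValueError("need one state per tip")
    arr = np.asarray(states)
    if not set(np.unique(arr)) <= {0, 1}:
        raise ValueError("states must be coded 0/1")
    return arr.astype(np.intp)


def _partials(tree: Phylogeny, states: np.ndarray, q: float) -> np.ndarray:
    """Postorder conditional likelihoods, one (2,) row per node."""
    part = np.ones((tree.n_nodes, 2))
    tip_of = {int(t): j for j, t in enumerate(tree.tips)}
    for v in tree.postorder():
        if v in tip_of:
            part[v] = 0.0
            part[v, states[tip_of[v]]] = 1.0
        else:
            for c in tree.children(v):
                P = _transition_matrix(q, tree.blen[c])
                part[v] *= P @ part[c]
    return part


def mk_loglik(tree: Phylogeny, tip_states, q: float, root_prior: str = "uniform") -> float:
    """Log-likelihood of binary tip states under the equal-rates Mk model.

    Felsenstein pruning with the analytic 2-state transition matrix.  The
    root prior is uniform (default) or stationary (identical for this
    symmetric model, kept for API clarity).  ``q = 0`` is allowed: the
    likelihood is 0.5 for concordant tips and 0 (-inf log) otherwise.
    """
    if q < 0:
        raise ValueError("rate q must be >= 0")
    if root_prior not in ("uniform", "stationary"):
        raise ValueError("root_prior must be 'uniform' or 'stationary'")
    states = _tip_state_array(tree, tip_states)
    part = _partials(tree, states, q)
    lik = 0.5 * part[0].sum()  # both priors are (1/2, 1/2) for symmetric Mk
    return float(np.log(lik)) if lik > 0 else -np.inf


@dataclass
class MkResults:
    """ML fit of the binary equal-rates Mk model."""

    q: float
    loglik: float
    n: int
    monomorphic: bool = False
    root_prior: str = "uniform"

    def summary(self) -> str:
        note = " (monomorphic tips: rate pinned at 0)" if self.monomorphic else ""
        return (
            f"2-state equal-rates Mk, n = {self.n} tips\n"
            f"  q    = {self.q:.6g} per unit time{note}\n"
            f"  ln L = {self.loglik:.4f}"
        )


class MkModel:
    """Binary-trait Mk model attached to a tree and tip states.

    ``tip_states`` is a dict label -> {0,1} or an array aligned with
    ``tree.tip_labels``.
    """

    def __init__(self, tree: Phylogeny, tip_states, root_prior: str = "uniform"):
        self.tree = tree
        self.states = _tip_state_array(tree, tip_states)
        self.root_prior = root_prior

    def loglik(self, q: float) -> float:
        return mk_loglik(self.tree, self.states, q, self.root_prior)

    def fit(self, q_max: float | None = None) -> MkResults:
        """ML transition rate by bounded 1-D optimization (deterministic).

        Monomorphic tip data put the optimum at the q = 0 boundary; the fit
        is returned with ``monomorphic=True`` rather than raising.
        """
        n = self.tree.n_tips
        if len(np.unique(self.states)) == 1:
            return MkResults(
                q=0.0, loglik=self.loglik(0.0), n=n, monomorphic=True,
                root_prior=self.root_prior,
            )
        T = float(self.tree.tip_depths().max())
        hi = q_max if q_max is not None else 100.0 / T
        res = optimize.minimize_scalar(
            lambda u: -self.loglik(float(np.exp(u))),
            bounds=(np.log(1e-8 / T), np.log(hi)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        q_hat = float(np.exp(res.x))
        return MkResults(
            q=q_hat, loglik=float(-res.fun), n=n, root_prior=self.root_prior
        )

    def stochastic_map(self, q: float, n_maps: int, seed: int = 0,
                       max_rejects: int = 10**6):
        return stochastic_map(
            self.tree, self.states, q, n_maps, seed=seed,
            root_prior=self.root_prior, max_rejects=max_rejects,
        )


def fit_mk(tree: Phylogeny, tip_states, root_prior: str = "uniform") -> MkResults:
    """Convenience wrapper: ML rate for the binary equal-rates Mk model."""
    return MkModel(tree, tip_states, root_prior=root_prior).fit()


# ----------------------------------------------------------------------
# stochastic mapping
# ----------------------------------------------------------------------
@dataclass
class SimmapHistory:
    """One sampled character history.

    ``node_states[v]`` is the sampled state at node v.  ``events[v]`` lists
    ``(time_from_parent, new_state)`` changes along the branch above v, in
    order; tips keep their observed states.
    """

    node_states: np.ndarray
    events: dict[int, list[tuple[float, int]]] = field(default_factory=dict)

    def n_changes(self) -> int:
        return sum(len(e) for e in self.events.values())

    def event_table(self, tree: Phylogeny) -> pd.DataFrame:
        rows = []
        for v, evs in sorted(self.events.items()):
            for t, s in evs:
                rows.append({"node": v, "time_from_parent": t, "new_state": s})
        return pd.DataFrame(rows, columns=["node", "time_from_parent", "new_state"])

    def to_simmap_newick(self, tree: Phylogeny) -> str:
        """Annotated Newick with {state,duration:...} branch maps."""

        def seg_string(v):
            b = tree.blen[v]
            state = self.node_states[tree.parent[v]]
            segs, last = [], 0.0
            for t, s in self.events.get(v, []):
                segs.append((state, t - last))
                state, last = s, t
            segs.append((state, b - last))
            return "{" + ":".join(f"{s},{d:.8g}" for s, d in segs) + "}"

        def rec(v):
            kids = tree.children(v)
            inner = "(" + ",".join(rec(c) for c in kids) + ")" if kids else ""
            lab = tree.labels.get(v, "")
            br = "" if v == 0 else f":{seg_string(v)}"
            return f"{inner}{lab}{br}"

        return rec(0) + ";"


def _sample_branch_history(q, t, a, b, rng, max_rejects):
    """Change times on one branch conditional on endpoint states a -> b.

    Rejection sampling from the unconditional process, with an exact
    uniformization fallback.  For the 2-state symmetric chain the
    uniformized jump chain is the pure state-swap, so every auxiliary jump
    is a real change and only the jump count's parity must match.
    """
    if q == 0.0:
        if a != b:
            raise RuntimeError("q = 0 cannot connect differing endpoint states")
        return []
    for _ in range(max_rejects):
        times, state, now = [], a, 0.0
        while True:
            now += rng.exponential(1.0 / q)
            if now >= t:
                break
            state = 1 - state
            times.append(now)
        if state == b:
            return [(tt, (a + i + 1) % 2) for i, tt in enumerate(times)]
    # uniformization fallback: P(N = m | a -> b) ∝ Poisson(qt)[m], parity-matched
    parity = (a + b) % 2
    m_max = max(10, int(q * t + 10.0 * np.sqrt(q * t) + 20))
    ms = np.arange(m_max + 1)
    logw = ms * np.log(q * t) - (q * t) - np.array(
        [np.sum(np.log(np.arange(1, m + 1))) if m else 0.0 for m in ms]
    )
    w = np.where(ms % 2 == parity, np.exp(logw - logw.max()), 0.0)
    if w.sum() == 0:
        raise RuntimeError(f"no parity-consistent change count on branch (qt={q*t})")
    m = int(rng.choice(ms, p=w / w.sum()))
    times = np.sort(rng.uniform(0.0, t, size=m))
    return [(float(tt), (a + i + 1) % 2) for i, tt in enumerate(times)]


def stochastic_map(
    tree: Phylogeny,
    tip_states,
    q: float,
    n_maps: int,
    seed: int = 0,
    root_prior: str = "uniform",
    max_rejects: int = 10**6,
    full_histories: bool = True,
) -> tuple[list[SimmapHistory], pd.DataFrame]:
    """Sample character histories conditional on the tip states.

    Returns the list of histories and a node-by-state frequency table
    (rows sum to 1) whose entries estimate the marginal posterior ancestral
    state probabilities.  ``full_histories=False`` samples node states only
    (events left empty), which is enough for the frequency table.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    states = _tip_state_array(tree, tip_states)
    part = _partials(tree, states, q)
    rng = np.random.default_rng(seed)
    n = tree.n_nodes
    tip_set = set(int(t) for t in tree.tips)
    counts = np.zeros((n, 2))
    maps = []
    root_pi = np.array([0.5, 0.5])
    # cache transition matrices (branch lengths repeat rarely, but cheap anyway)
    P = {v: _transition_matrix(q, tree.blen[v]) for v in range(1, n)}
    for _ in range(n_maps):
        node_state = np.empty(n, dtype=np.intp)
        w = root_pi * part[0]
        node_state[0] = rng.choice(2, p=w / w.sum())
        for v in range(1, n):
            if v in tip_set:
                node_state[v] = states[np.where(tree.tips == v)[0][0]]
                continue
            pa = node_state[tree.parent[v]]
            w = P[v][pa] * part[v]
            node_state[v] = rng.choice(2, p=w / w.sum())
        # tips are fixed, but their branch histories must still connect them
        counts[np.arange(n), node_state] += 1
        events = {}
        if full_histories:
            for v in range(1, n):
                events[v] = _sample_branch_history(
                    q, tree.blen[v], node_state[tree.parent[v]],
                    node_state[v], rng, max_rejects,
                )
        maps.append(SimmapHistory(node_states=node_state, events=events))
    freq = pd.DataFrame(
        counts / n_maps,
        columns=["state0", "state1"],
        index=pd.Index(range(n), name="node"),
    )
    return maps, freq


def marginal_ancestral_probs(
    tree: Phylogeny, tip_states, q: float, root_prior: str = "uniform"
) -> pd.DataFrame:
    """Exact marginal ancestral state probabilities per node.

    Standard up-down pass (conditional likelihoods times outside
    likelihoods); the large-n limit of stochastic-map node frequencies.
    """
    states = _tip_state_array(tree, tip_states)
    part = _partials(tree, states, q)
    n = tree.n_nodes
    out = np.zeros((n, 2))
    out[0] = np.array([0.5, 0.5]) * part[0]
    down = np.zeros((n, 2))
    down[0] = np.array([0.5, 0.5])
    for v in range(1, n):
        pa = tree.parent[v]
        P = _transition_matrix(q, tree.blen[v])
        sib = down[pa].copy()
        for c in tree.children(pa):
            if c != v:
                Pc = _transition_matrix(q, tree.blen[c])
                sib *= Pc @ part[c]
        down[v] = sib @ P
        out[v] = down[v] * part[v]
    out /= out.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        out, columns=["state0", "state1"], index=pd.Index(range(n), name="node")
    )
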