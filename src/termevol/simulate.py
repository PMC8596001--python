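"""Synthetic fossil-bearing datasets with the structure the analysis assumes.

Forward-time birth–death trees whose extinct lineages can be retained as
fossil tips (making the tree non-ultrametric), genus-structured species
tables with within-genus trait variation, tip traits drawn exactly from the
multivariate normal each candidate model defines, caste values generated
from configurable disparity offsets, and binary/ternary social traits
evolved by a forward Mk process.

Every generator takes an explicit seed or Generator; identical seeds give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import models as mdl
from .tree import Phylogeny, RegimePainting

__all__ = [
    "SimConfig",
    "simulate_bd_tree",
    "simulate_trait",
    "simulate_discrete",
    "simulate_species_table",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation settings.

    The defaults emulate the shape of a genus-level termite dataset: ~113
    modern genus tips plus a few dozen retained fossil tips, around three
    measured species per genus with modest within-genus spread on the ln
    scale, positive imago-vs-worker size disparity, soldiers slightly larger
    than imagoes on average, and a handful of social-trait transitions
    across the tree.
    """

    birth: float = 1.0
    death: float = 0.5
    n_extant: int = 113
    fossil_retention: float = 0.5
    mean_species_per_genus: float = 3.0
    within_genus_sd: float = 0.15  # sd of ln head width among congeners
    model: str = "kappa"
    params: dict = None  # sigma2, z0, and the model's shape/trend parameter
    mk_rate: float = 0.1  # per-unit-time social-trait transition rate
    disparity_worker: tuple[float, float] = (0.25, 0.25)  # mean, sd
    disparity_soldier: tuple[float, float] = (-0.10, 0.25)
    seed: int = 0

    def __post_init__(self):
        if self.birth <= 0:
            raise ValueError("birth rate must be positive")
        if self.death < 0 or not 0 <= self.fossil_retention <= 1:
            raise ValueError("death >= 0 and retention in [0, 1] required")
        if self.params is None:
            object.__setattr__(
                self, "params", {"sigma2": 0.05, "z0": 0.84, "kappa": 0.2}
            )


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------
def simulate_bd_tree(
    config: SimConfig, rng: np.random.Generator | int | None = None,
    max_tries: int = 1000,
) -> Phylogeny:
    """Forward-time birth–death tree conditioned on the extant tip count.

    The simulation runs until ``n_extant`` lineages are simultaneously
    alive; extant tips all end at that moment.  Each extinct lineage is
    kept as a fossil tip with probability ``fossil_retention`` (its tip
    ends at its extinction time), otherwise it is pruned away.  Whole-clade
    extinction triggers a resample, up to ``max_tries``.

    Extant tips are labelled ``Gen001``... (genus-level); retained fossil
    tips ``Fosgen1_sp``... (species-level), so the genus tokens of modern
    and fossil labels never collide.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else int(rng))
    b, d, target = config.birth, config.death, config.n_extant
    if target < 2:
        raise ValueError("need at least 2 extant tips")
    for _ in range(max_tries):
        nodes = _gillespie(b, d, target, rng)
        if nodes is None:
            continue
        tree = _nodes_to_tree(nodes)
        extinct = [
            l for l in tree.tip_labels if l.startswith("x")
        ]
        keep_fossil = [
            l for l in extinct if rng.random() < config.fossil_retention
        ]
        extant = [l for l in tree.tip_labels if not l.startswith("x")]
        tree = tree.prune_to(extant + keep_fossil)
        return _relabel(tree)
    raise RuntimeError(f"no surviving tree in {max_tries} attempts")


def _gillespie(b, d, target, rng):
    # each lineage: [start_time, end_time|None, parent_index, alive]
    start = [0.0]
    end = [None]
    parent = [-1]
    alive = [0]
    t = 0.0
    while len(alive) < target:
        if not alive:
            return None
        rate = len(alive) * (b + d)
        t += rng.exponential(1.0 / rate)
        i = alive[rng.integers(len(alive))]
        if rng.random() < b / (b + d):
            for _ in range(2):
                start.append(t)
                end.append(None)
                parent.append(i)
                alive.append(len(start) - 1)
            end[i] = t
            alive.remove(i)
        else:
            end[i] = t
            alive.remove(i)
    # sample the observation time uniformly within the period that has
    # exactly `target` lineages (otherwise the last two tips have length 0)
    t += rng.exponential(1.0 / (len(alive) * (b + d)))
    for i in alive:
        end[i] = t
    return list(zip(start, end, parent))


def _nodes_to_tree(nodes) -> Phylogeny:
    children = {}
    for i, (_, _, pa) in enumerate(nodes):
        children.setdefault(pa, []).append(i)
    t_stop = max(e for _, e, _ in nodes)
    n_ext = n_fos = 0
    parent_out, blen_out, labels = [], [], {}
    index = {}

    def visit(i, pa_new):
        nonlocal n_ext, n_fos
        start, endt, _ = nodes[i]
        idx = len(parent_out)
        index[i] = idx
        parent_out.append(pa_new)
        blen_out.append(endt - start)
        kids = children.get(i, [])
        if not kids:
            if endt >= t_stop - 1e-12:
                n_ext += 1
                labels[idx] = f"Gen{n_ext:03d}"
            else:
                n_fos += 1
                labels[idx] = f"xfos{n_fos}_sp"  # 'x' marks extinct, relabelled later
        for c in kids:
            visit(c, idx)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(nodes) + 1000))
    try:
        visit(0, -1)
    finally:
        sys.setrecursionlimit(old)
    blen_out[0] = 0.0
    return Phylogeny(parent_out, blen_out, labels)


def _relabel(tree: Phylogeny) -> Phylogeny:
    labels = dict(tree.labels)
    k = 0
    for v, lab in sorted(labels.items()):
        if lab.startswith("x"):
            k += 1
            labels[v] = f"Fosgen{k}_sp"
    return Phylogeny(tree.parent.copy(), tree.blen.copy(), labels)


# ----------------------------------------------------------------------
# traits
# ----------------------------------------------------------------------
def simulate_trait(
    tree: Phylogeny,
    model: str,
    params: dict,
    painting: RegimePainting | None = None,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """One exact draw of tip values from a model's multivariate normal.

    ``params`` must name ``sigma2``, ``z0`` and the model's shape parameter
    (or ``mu`` for the trend models).  Sampling goes through the same
    mean/covariance construction the likelihood uses, via a Cholesky factor.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    shape_name = mdl.SHAPE_PARAM[model]
    shape = None if shape_name in (None, "mu") else params[shape_name]
    D, V0 = mdl.model_mean_design_cov(model, tree, shape=shape, painting=painting)
    beta = [params["z0"]]
    if model in ("trend", "trend_BM"):
        beta.append(params["mu"])
    mean = D @ np.asarray(beta)
    sigma2 = params["sigma2"]
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if sigma2 == 0:
        return mean.copy()
    V = sigma2 * V0
    # tiny jitter guards exactly-singular covariances (duplicate zero branches)
    L = np.linalg.cholesky(V + 1e-12 * np.trace(V) / len(V) * np.eye(len(V)))
    return mean + L @ rng.standard_normal(tree.n_tips)


def simulate_discrete(
    tree: Phylogeny,
    n_states: int = 2,
    rate: float = 0.1,
    rng: np.random.Generator | int = 0,
    root_state: int | None = None,
) -> dict[str, int]:
    """Forward simulation of an equal-rates Mk character; tip states by label.

    ``rate`` is the transition rate to each other state, so the total
    leaving rate is ``rate * (n_states - 1)``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    leave = rate * (n_states - 1)
    state = np.empty(tree.n_nodes, dtype=np.intp)
    state[0] = rng.integers(n_states) if root_state is None else root_state
    for v in range(1, tree.n_nodes):
        s = state[tree.parent[v]]
        t = 0.0
        while leave > 0:
            t += rng.exponential(1.0 / leave)
            if t >= tree.blen[v]:
                break
            others = [k for k in range(n_states) if k != s]
            s = others[rng.integers(n_states - 1)]
        state[v] = s
    return {tree.labels[int(v)]: int(state[int(v)]) for v in tree.tips}


# ----------------------------------------------------------------------
# species tables
# ----------------------------------------------------------------------
_NESTING = ("one_piece", "multiple_piece", "separate_piece")
_WTYPE = ("pseudergate", "true_worker")


def simulate_species_table(
    tree: Phylogeny,
    config: SimConfig,
    genus_values: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Expand genus tips into a species-level trait table with castes.

    Each modern (genus-level) tip becomes 1 + Poisson species whose imago
    ln head widths scatter around the tip's trait value with the configured
    within-genus sd.  Worker and soldier values derive from the imago value
    through proportional-disparity offsets d: caste = imago / (1 + d), so
    the realized disparity (imago - caste)/caste equals d by construction.
    Worker type (binary) and nesting type (ternary) evolve by forward Mk on
    the tree; colony sizes are lognormal.  Fossil tips contribute a single
    imago record each, as in the fossil record.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else int(rng))
    if genus_values is None:
        painting = None
        genus_values = simulate_trait(tree, config.model, config.params, painting, rng)
    genus_values = np.asarray(genus_values, dtype=float)
    if genus_values.size != tree.n_tips:
        raise ValueError("need one genus-level trait value per tip")
    wtype = simulate_discrete(tree, 2, config.mk_rate, rng)
    nest = simulate_discrete(tree, 3, config.mk_rate, rng)
    dm_w, ds_w = config.disparity_worker
    dm_s, ds_s = config.disparity_soldier
    rows = []
    for j, label in enumerate(tree.tip_labels):
        fossil = "_" in label
        genus = label.split("_")[0]
        family = "Simfamily"
        if fossil:
            rows.append(
                dict(
                    species=label, genus=genus, family=family, caste="imago",
                    head_width_mm=float(np.exp(genus_values[j])), status="fossil",
                    worker_type=np.nan, nesting_type=np.nan, max_colony_size=np.nan,
                )
            )
            continue
        n_sp = 1 + rng.poisson(max(config.mean_species_per_genus - 1.0, 0.0))
        wt = _WTYPE[wtype[label]]
        nt = _NESTING[nest[label]]
        colony = float(np.round(np.exp(rng.normal(9.0, 2.0))))
        for s in range(n_sp):
            ln_im = genus_values[j] + rng.normal(0.0, config.within_genus_sd)
            imago = float(np.exp(ln_im))
            d_w = max(rng.normal(dm_w, ds_w), -0.9)
            d_s = max(rng.normal(dm_s, ds_s), -0.9)
            common = dict(
                genus=genus, family=family, status="modern",
                worker_type=wt, nesting_type=nt, max_colony_size=colony,
            )
            sp = f"{genus}_sp{s + 1}"
            rows.append(dict(species=sp, caste="imago", head_width_mm=imago, **common))
            rows.append(
                dict(species=sp, caste="worker" if wt == "true_worker" else "pseudergate",
                     head_width_mm=imago / (1.0 + d_w), **common)
            )
            rows.append(
                dict(species=sp, caste="soldier", head_width_mm=imago / (1.0 + d_s), **common)
            )
    cols = [
        "species", "genus", "family", "caste", "head_width_mm", "status",
        "worker_type", "nesting_type", "max_colony_size",
    ]
    return pd.DataFrame(rows)[cols]


def simulate_dataset(
    config: SimConfig, painting_clade: bool = False
) -> tuple[Phylogeny, pd.DataFrame, np.ndarray]:
    """Tree + species table + true genus-level trait values, one call.

    With ``painting_clade=True`` the trait is generated under the clade-
    mixed trend/BM model, with the BM regime painted on the larger child
    clade of the root (a stand-in for the higher-termite clade).
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_bd_tree(config, rng)
    painting = None
    if painting_clade:
        painting = default_clade_painting(tree)
    values = simulate_trait(tree, config.model, config.params, painting, rng)
    table = simulate_species_table(tree, config, genus_values=values, rng=rng)
    return tree, table, values


def default_clade_painting(tree: Phylogeny) -> RegimePainting:
    """Paint the clade closest to half the tips as the BM regime.

    A deterministic stand-in for designating one species-rich derived clade
    (the higher termites in the real analysis) as the non-trending regime:
    among all internal nodes, the one whose descendant tip count is nearest
    to half the tree (ties to the earlier node) defines the crown group.
    """
    from .tree import paint_clade

    M = tree.incidence()
    sizes = M.sum(axis=1)
    target = tree.n_tips / 2.0
    internal = [v for v in range(1, tree.n_nodes) if tree.children(v)]
    best = min(internal, key=lambda v: (abs(sizes[v] - target), v))
    tip_idx = np.where(M[best])[0]
    return paint_clade(tree, [tree.tip_labels[i] for i in tip_idx])
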