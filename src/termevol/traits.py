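"""Trait tables: reading, measurement curation, tree matching, subsampling.

Head-width records are species-by-caste rows.  One representative value per
(species, caste) is obtained by a fixed priority among the ways a source can
report size — a species mean beats a midrange (computed from a reported
min–max span) beats a holotype measurement — and values from multiple
sources are averaged.  For castes with within-species polymorphism the
largest subcaste is used by default.

Modern taxa are analysed at genus level (one tip per genus), fossil taxa at
species level, so matching a table to a tree and drawing one-species-per-
genus subsamples are first-class operations here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tree import Phylogeny

__all__ = [
    "SourceReport",
    "curate_measurement",
    "read_trait_table",
    "match_tree_and_traits",
    "subsample_one_per_genus",
    "MatchedDataset",
]

log = logging.getLogger(__name__)

CASTES = ("imago", "soldier", "worker", "pseudergate")
STATUSES = ("modern", "fossil")
WORKER_TYPES = ("true_worker", "pseudergate")
NESTING_TYPES = ("one_piece", "multiple_piece", "separate_piece")

TRAIT_COLUMNS = (
    "species",
    "genus",
    "family",
    "caste",
    "head_width_mm",
    "status",
)


@dataclass(frozen=True)
class SourceReport:
    """One literature report of a caste's head width for a species.

    Exactly the fields that are present are used, in the priority order
    mean > (min, max) midrange > holotype.  For polymorphic castes a report
    may carry subcaste values keyed by subcaste name; the largest (or, on
    request, smallest) subcaste is selected before the priority rule.
    """

    mean: float | None = None
    range: tuple[float, float] | None = None
    holotype: float | None = None
    subcastes: Mapping[str, "SourceReport"] | None = None
    eyes_included: bool | None = None  # None = authors silent; recorded only


def _report_value(r: SourceReport, largest_subcaste: bool) -> tuple[float, str]:
    if r.subcastes:
        # pick the subcaste with the extreme representative value
        vals = {
            k: _report_value(v, largest_subcaste) for k, v in r.subcastes.items()
        }
        key = (max if largest_subcaste else min)(vals, key=lambda k: vals[k][0])
        return vals[key]
    if r.mean is not None:
        value, basis = float(r.mean), "mean"
    elif r.range is not None:
        lo, hi = r.range
        if hi < lo:
            raise ValueError(f"range max {hi} below min {lo}")
        value, basis = (float(lo) + float(hi)) / 2.0, "midrange"
    elif r.holotype is not None:
        value, basis = float(r.holotype), "holotype"
    else:
        raise ValueError("source report carries no measurement")
    if not value > 0:
        raise ValueError(f"non-positive head width {value}")
    return value, basis


def curate_measurement(
    reports: Sequence[SourceReport], largest_subcaste: bool = True
) -> dict:
    """Collapse per-source reports into one representative head width.

    Within each source the priority rule picks one value; values are then
    averaged across sources.  Returns the value, the basis of the
    highest-priority source used, the number of sources, and whether any
    source was silent about eye inclusion (a provenance flag only — it
    cannot be validated from the data).
    """
    if not reports:
        raise ValueError("no source reports given")
    values, bases = [], []
    for r in reports:
        v, b = _report_value(r, largest_subcaste)
        values.append(v)
        bases.append(b)
    priority = {"mean": 0, "midrange": 1, "holotype": 2}
    best = min(bases, key=priority.__getitem__)
    return {
        "head_width_mm": float(np.mean(values)),
        "measurement_basis": best,
        "n_sources": len(values),
        "eyes_assumed": any(r.eyes_included is None for r in reports),
    }


# ----------------------------------------------------------------------
# delimited-table IO
# ----------------------------------------------------------------------
def read_trait_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a species-level trait table (CSV or TSV, dialect auto-detected).

    Required columns: species, genus, family, caste, head_width_mm, status.
    Optional: worker_type, nesting_type, max_colony_size.  Vocabulary and
    positivity constraints are validated; underscores and spaces in species
    names are normalized to underscores with the mapping logged.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    df = df.copy()
    for col in ("species", "genus", "family"):
        normalized = df[col].astype(str).str.strip().str.replace(" ", "_")
        changed = df[col].astype(str) != normalized
        if changed.any():
            pairs = list(zip(df.loc[changed, col], normalized[changed]))
            log.info("normalized %d labels in %s: %s", changed.sum(), col, pairs[:5])
        df[col] = normalized
    bad_caste = set(df["caste"]) - set(CASTES)
    if bad_caste:
        raise ValueError(f"unknown caste values: {sorted(bad_caste)}")
    bad_status = set(df["status"]) - set(STATUSES)
    if bad_status:
        raise ValueError(f"unknown status values: {sorted(bad_status)}")
    if (df["head_width_mm"] <= 0).any():
        bad = df.loc[df["head_width_mm"] <= 0, "species"].tolist()
        raise ValueError(f"non-positive head widths for: {bad}")
    if "worker_type" in df.columns:
        bad = set(df["worker_type"].dropna()) - set(WORKER_TYPES)
        if bad:
            raise ValueError(f"unknown worker_type values: {sorted(bad)}")
    if "nesting_type" in df.columns:
        bad = set(df["nesting_type"].dropna()) - set(NESTING_TYPES)
        if bad:
            raise ValueError(f"unknown nesting_type values: {sorted(bad)}")
    if "max_colony_size" in df.columns:
        sizes = df["max_colony_size"].dropna()
        if (sizes <= 0).any():
            raise ValueError("max_colony_size must be positive where present")
    dup = df.duplicated(subset=["species", "caste"])
    if dup.any():
        raise ValueError(
            f"duplicate (species, caste) rows: "
            f"{df.loc[dup, ['species', 'caste']].values.tolist()}"
        )
    return df


def write_trait_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)


# ----------------------------------------------------------------------
# matching tables to trees
# ----------------------------------------------------------------------
@dataclass
class MatchedDataset:
    """A pruned tree and an aligned ln-trait vector (one value per tip).

    Modern tips are genus-level (value = mean ln head width over the genus's
    species, or one subsampled species); fossil tips are species-level.
    """

    tree: Phylogeny
    values: np.ndarray  # ln head width, aligned with tree.tip_labels
    caste: str
    level: str
    genus_species: dict[str, list[str]] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.tree.n_tips:
            raise ValueError("one trait value per tip required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait values must be finite")

    @property
    def n(self) -> int:
        return self.tree.n_tips

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.tree.tip_labels, name="ln_head_width")


def _tip_genus(label: str) -> str:
    """Genus token of a tip label ('Genus_species' or bare 'Genus')."""
    return label.split("_")[0]


def match_tree_and_traits(
    tree: Phylogeny,
    records: pd.DataFrame,
    caste: str = "imago",
    include_fossils: bool = True,
    log_scale: bool = True,
) -> MatchedDataset:
    """Prune tree and table to their shared taxa and align trait values.

    Modern tips are matched at genus level by the genus token of the tip
    label and receive the mean ln head width across the genus's measured
    species; fossil tips are matched by full species name.  Tips without
    data and data without tips are dropped.
    """
    if caste not in CASTES:
        raise ValueError(f"caste must be one of {CASTES}")
    sub = records[records["caste"] == caste]
    if not include_fossils:
        sub = sub[sub["status"] == "modern"]
    if sub.empty:
        raise ValueError(f"no {caste} records to match")
    modern = sub[sub["status"] == "modern"]
    fossil = sub[sub["status"] == "fossil"]
    transform = np.log if log_scale else np.asarray
    genus_value = modern.groupby("genus")["head_width_mm"].apply(
        lambda v: float(np.mean(transform(v.to_numpy())))
    )
    species_value = {
        r.species: float(transform(np.atleast_1d(r.head_width_mm))[0])
        for r in fossil.itertuples()
    }
    genus_species = {
        g: sorted(grp["species"]) for g, grp in modern.groupby("genus")
    }

    keep, values = [], []
    for label in tree.tip_labels:
        if label in species_value:  # fossil, species-level
            keep.append(label)
            values.append(species_value[label])
        else:
            g = _tip_genus(label)
            if g in genus_value.index:
                keep.append(label)
                values.append(genus_value[g])
    if len(keep) < 3:
        raise ValueError(
            f"only {len(keep)} tree tips have {caste} data; cannot analyse"
        )
    dropped_tips = set(tree.tip_labels) - set(keep)
    if dropped_tips:
        log.info("dropped %d tips without %s data", len(dropped_tips), caste)
    pruned = tree.prune_to(keep)
    order = [keep.index(l) for l in pruned.tip_labels]
    return MatchedDataset(
        tree=pruned,
        values=np.asarray(values)[order],
        caste=caste,
        level="genus+fossil" if include_fossils else "genus",
        genus_species=genus_species,
    )


def subsample_one_per_genus(
    records: pd.DataFrame,
    rng: np.random.Generator | int,
    caste: str = "imago",
) -> pd.DataFrame:
    """Draw one species per modern genus uniformly at random.

    Fossil records are always carried through unchanged.  Genera with no
    measured species for the caste simply contribute nothing (logged).
    Deterministic for a fixed Generator state or integer seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    sub = records[records["caste"] == caste]
    fossil = sub[sub["status"] == "fossil"]
    modern = sub[sub["status"] == "modern"]
    rows = []
    for genus, grp in sorted(modern.groupby("genus"), key=lambda kv: kv[0]):
        grp = grp.sort_values("species")
        rows.append(grp.iloc[rng.integers(len(grp))])
    if not rows and fossil.empty:
        raise ValueError(f"no {caste} records to subsample")
    picked = pd.DataFrame(rows) if rows else modern.iloc[:0]
    return pd.concat([picked, fossil], ignore_index=True)
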