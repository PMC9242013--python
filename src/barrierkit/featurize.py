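"""Feature-table assembly and preprocessing.

Per-reaction descriptor vectors are collected into level- and subset-tagged
tables ("MA", "TS", or "All", the last including the baseline barrier at the
table's level), standardised with train-only statistics, and pruned of
zero-variance and collinear columns.  Missing descriptors exclude the
reaction row — nothing is imputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import descriptors as D
from . import thermo
from .qm_io import ReactionRecord

logger = logging.getLogger(__name__)

SUBSETS = ("MA", "TS", "All")


@dataclass
class FeatureTable:
    """A reactions x features matrix plus targets, tags and metadata.

    ``frame`` holds raw (or standardised) feature columns indexed by
    reaction id; ``baseline`` names the SQM-barrier column used by delta
    models; ``standardization`` maps feature -> (mean, sd) once applied.
    """

    frame: pd.DataFrame
    level: str = ""
    subset: str = "All"
    target: pd.Series | None = None
    split: pd.Series | None = None
    baseline: str | None = None
    standardization: dict[str, tuple[float, float]] | None = None
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if self.split is None:
            self.split = pd.Series("unassigned", index=self.frame.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def select_rows(self, ids: Sequence) -> "FeatureTable":
        ids = list(ids)
        return replace(
            self,
            frame=self.frame.loc[ids],
            target=self.target.loc[ids] if self.target is not None else None,
            split=self.split.loc[ids],
            exclusions=list(self.exclusions),
        )

    def rows_with_tag(self, tag: str) -> list:
        return list(self.split.index[self.split == tag])


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _species_key_map(reaction: ReactionRecord, role: str) -> dict[str, int]:
    ka = reaction.key_atoms
    assert ka is not None
    out = {
        "beta_carbon": ka.beta_carbon,
        "carbonyl_oxygen": ka.carbonyl_oxygen,
    }
    for k, idx in enumerate(ka.core):
        out[f"core{k}"] = idx
    if role == "TS":
        out["nucleophile_carbon"] = ka.nucleophile_carbon
    return out


def _rgroup_pairs(
    reaction: ReactionRecord, structure, bonds
) -> dict[str, tuple[int, int]]:
    ka = reaction.key_atoms
    assert ka is not None
    adj = bonds.adjacency()
    core = set(ka.core)
    out = {}
    for k, attach in enumerate(ka.rgroup_attachments):
        anchors = sorted(adj[attach] & core)
        if not anchors:
            raise ValueError(f"R-group atom {attach} not bonded to the core")
        out[f"R{k + 1}"] = (anchors[0], attach)
    return out


def assemble(
    reactions: Sequence[ReactionRecord],
    level: str,
    subset: str = "All",
    target_level: str | None = "DFT",
    temperature: float = 298.15,
    concentration: float = 1.0,
) -> FeatureTable:
    """Build one row of named descriptors per reaction.

    Subset "MA" uses Michael-acceptor descriptors only, "TS" transition-state
    descriptors only, "All" both plus the level's activation barrier as a
    feature.  The target column is the ``target_level`` barrier when that
    level's records are present.
    """
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}")
    roles = {"MA": ("MA",), "TS": ("TS",), "All": ("MA", "TS")}[subset]
    rows: dict[str, dict[str, float]] = {}
    targets: dict[str, float] = {}
    splits: dict[str, str] = {}
    exclusions: list[tuple[str, str]] = []
    for reaction in reactions:
        try:
            if reaction.key_atoms is None:
                raise ValueError("no key atoms")
            values: dict[str, float] = {}
            for role in roles:
                rec = reaction.get(level, role)
                s = rec.structure
                bonds = D.perceive_bonds(s)
                dset = D.compute_descriptor_set(
                    s,
                    key_atom_map=_species_key_map(reaction, role),
                    rgroup_attachments=_rgroup_pairs(reaction, s, bonds),
                    mulliken=rec.mulliken,
                    level=level,
                    bonds=bonds,
                )
                values.update({f"{role}:{k}": v for k, v in dset.values.items()})
            if subset == "All":
                barrier = thermo.activation_barrier(
                    reaction,
                    level,
                    temperature=temperature,
                    concentration=concentration,
                )
                values["barrier"] = barrier.dg_act
            bad = [k for k, v in values.items() if not np.isfinite(v)]
            if bad:
                raise ValueError(f"non-finite descriptors: {bad}")
        except (KeyError, ValueError) as exc:
            logger.warning("excluding reaction %s: %s", reaction.reaction_id, exc)
            exclusions.append((reaction.reaction_id, str(exc)))
            continue
        rows[reaction.reaction_id] = values
        splits[reaction.reaction_id] = reaction.split_tag
        if target_level is not None and all(
            reaction.has(target_level, r) for r in ("MA", "nucleophile", "TS")
        ):
            targets[reaction.reaction_id] = thermo.activation_barrier(
                reaction,
                target_level,
                temperature=temperature,
                concentration=concentration,
            ).dg_act
    frame = pd.DataFrame.from_dict(rows, orient="index")
    if frame.isna().any().any():
        # descriptor schema mismatch across rows: drop offending rows
        bad_rows = frame.index[frame.isna().any(axis=1)]
        for rid in bad_rows:
            exclusions.append((str(rid), "incomplete descriptor schema"))
        frame = frame.drop(index=bad_rows)
    target = pd.Series(targets).reindex(frame.index) if targets else None
    if target is not None and target.isna().any():
        missing = target.index[target.isna()]
        for rid in missing:
            exclusions.append((str(rid), "missing target barrier"))
        frame = frame.drop(index=missing)
        target = target.drop(index=missing)
    return FeatureTable(
        frame=frame,
        level=level,
        subset=subset,
        target=target,
        split=pd.Series(splits).reindex(frame.index),
        baseline="barrier" if subset == "All" else None,
        exclusions=exclusions,
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def standardize(table: FeatureTable, stats_rows: Sequence) -> FeatureTable:
    """Zero-mean/unit-variance transform with statistics from ``stats_rows``
    only (the train split); parameters are stored for reuse and inversion."""
    stats_rows = list(stats_rows)
    if not stats_rows:
        raise ValueError("stats_rows must be non-empty")
    sub = table.frame.loc[stats_rows]
    mean = sub.mean()
    sd = sub.std(ddof=0)
    zero_var = list(sd.index[sd <= 0.0])
    if zero_var:
        raise ValueError(
            f"zero-variance features reached standardization: {zero_var}"
        )
    params = {name: (float(mean[name]), float(sd[name])) for name in sub.columns}
    frame = (table.frame - mean) / sd
    return replace(table, frame=frame, standardization=params)


def apply_standardization(
    table: FeatureTable, params: dict[str, tuple[float, float]]
) -> FeatureTable:
    mean = pd.Series({k: v[0] for k, v in params.items()})
    sd = pd.Series({k: v[1] for k, v in params.items()})
    frame = (table.frame[list(params)] - mean) / sd
    return replace(table, frame=frame, standardization=dict(params))


def invert_standardization(table: FeatureTable) -> FeatureTable:
    if table.standardization is None:
        raise ValueError("table is not standardized")
    mean = pd.Series({k: v[0] for k, v in table.standardization.items()})
    sd = pd.Series({k: v[1] for k, v in table.standardization.items()})
    frame = table.frame * sd + mean
    return replace(table, frame=frame, standardization=None)


@dataclass(frozen=True)
class Removal:
    feature: str
    reason: str
    detail: str


def prune(
    table: FeatureTable,
    var_tol: float = 0.0,
    corr_threshold: float = 0.95,
    stats_rows: Sequence | None = None,
) -> tuple[FeatureTable, list[Removal]]:
    """Drop zero-variance then collinear features, deterministically.

    Variance and correlations are computed on ``stats_rows`` (default: all
    rows).  For each pair with |Pearson r| above the threshold the
    lexicographically later feature name is dropped.  The baseline barrier
    column is always retained.
    """
    rows = list(stats_rows) if stats_rows is not None else list(table.frame.index)
    sub = table.frame.loc[rows]
    removals: list[Removal] = []
    keep = list(table.frame.columns)
    variances = sub.var(ddof=0)
    for name in list(keep):
        if name == table.baseline:
            continue
        if variances[name] <= var_tol:
            keep.remove(name)
            removals.append(
                Removal(name, "zero_variance", f"var={variances[name]:.3e}")
            )
    corr = sub[keep].corr().abs()
    ordered = sorted(keep)
    dropped: set[str] = set()
    for a_i, name_a in enumerate(ordered):
        if name_a in dropped:
            continue
        for name_b in ordered[a_i + 1 :]:
            if name_b in dropped or name_b == table.baseline:
                continue
            r = corr.loc[name_a, name_b]
            if np.isfinite(r) and r > corr_threshold:
                dropped.add(name_b)
                removals.append(
                    Removal(name_b, "collinear", f"|r|={r:.4f} with {name_a}")
                )
    keep = [c for c in keep if c not in dropped]
    return replace(table, frame=table.frame[keep]), removals


# ---------------------------------------------------------------------------
# serialization (CSV + JSON sidecar)
# ---------------------------------------------------------------------------


def save_table(table: FeatureTable, path: str | Path) -> None:
    path = Path(path)
    frame = table.frame.copy()
    if table.target is not None:
        frame["__target__"] = table.target
    frame["__split__"] = table.split
    frame.to_csv(path, index_label="reaction_id")
    sidecar = {
        "level": table.level,
        "subset": table.subset,
        "baseline": table.baseline,
        "standardization": table.standardization,
        "exclusions": table.exclusions,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def load_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    frame = pd.read_csv(path, index_col="reaction_id")
    frame.index = frame.index.astype(str)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    target = None
    if "__target__" in frame.columns:
        target = frame.pop("__target__")
    split = frame.pop("__split__")
    std = sidecar.get("standardization")
    if std is not None:
        std = {k: (float(v[0]), float(v[1])) for k, v in std.items()}
    return FeatureTable(
        frame=frame,
        level=sidecar["level"],
        subset=sidecar["subset"],
        target=target,
        split=split,
        baseline=sidecar.get("baseline"),
        standardization=std,
        exclusions=[tuple(e) for e in sidecar.get("exclusions", [])],
    )
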