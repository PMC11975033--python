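"""Group-level connectivity maps from normalized innervation fractions.

For each experimental group the per-animal innervation fractions are averaged
(mean ± SEM across animals, with regions absent in an animal counted as zero
for that animal) and turned into a star-shaped connectivity map under three
thresholds, all strict:

* a region appears as a node iff its group-mean fraction exceeds the inclusion
  threshold (default > 1 % of signal);
* it receives an edge iff the mean exceeds the edge threshold (default > 5 %);
* edge thickness scales linearly with the mean percentage, saturating at the
  cap (default 20 %): thickness = min(mean %, cap) / cap ∈ (0, 1].

Bubble values per node equal the group-mean fraction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

DEFAULT_INCLUDE_PCT = 1.0
DEFAULT_EDGE_PCT = 5.0
DEFAULT_CAP_PCT = 20.0


@dataclass(frozen=True)
class GroupRegionStat:
    group: str
    region_id: int
    mean_fraction: float
    sem: float | None
    n_animals: int

    def __post_init__(self):
        if not 0.0 <= self.mean_fraction <= 1.0:
            raise ValueError(f"mean_fraction must be in [0, 1], got {self.mean_fraction}")
        if self.sem is not None and self.sem < 0:
            raise ValueError("sem must be ≥ 0")


@dataclass
class ConnectivityMap:
    group: str
    nodes: list[dict] = field(default_factory=list)   # {region_id, mean_fraction, sem, bubble}
    edges: list[dict] = field(default_factory=list)   # {region_id, strength_pct, thickness}
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "thresholds": self.thresholds,
            "nodes": self.nodes,
            "edges": self.edges,
        }


def group_means(fractions: pd.DataFrame) -> list[GroupRegionStat]:
    """Mean ± SEM of innervation fractions per (group, region) across animals.

    Input columns: group, animal_id, region_id, norm_fraction. A (group,
    region) pair missing for some animal of that group is imputed as fraction
    zero for that animal before averaging — omitting it would bias group means
    upward. Single-animal groups report SEM None with a warning.
    """
    required = {"group", "animal_id", "region_id", "norm_fraction"}
    missing = required - set(fractions.columns)
    if missing:
        raise ValueError(f"fraction table missing columns: {sorted(missing)}")

    stats: list[GroupRegionStat] = []
    for grp, sub in fractions.groupby("group", sort=True):
        animals = sorted(sub["animal_id"].unique())
        regions = sorted(sub["region_id"].unique())
        wide = (
            sub.pivot_table(index="animal_id", columns="region_id",
                            values="norm_fraction", aggfunc="sum")
            .reindex(index=animals, columns=regions)
        )
        n_imputed = int(wide.isna().to_numpy().sum())
        if n_imputed:
            logger.info("group %s: %d missing (animal, region) fractions imputed as 0", grp, n_imputed)
        wide = wide.fillna(0.0)
        n = len(animals)
        if n == 1:
            warnings.warn(f"group {grp!r} has a single animal; SEM undefined", stacklevel=2)
        for region in regions:
            vals = wide[region].to_numpy(dtype=float)
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else None
            stats.append(GroupRegionStat(str(grp), int(region), float(vals.mean()), sem, n))
    return stats


def build_map(
    stats: list[GroupRegionStat],
    include_pct: float = DEFAULT_INCLUDE_PCT,
    edge_pct: float = DEFAULT_EDGE_PCT,
    cap_pct: float = DEFAULT_CAP_PCT,
) -> list[ConnectivityMap]:
    """Apply the strict inclusion/edge/cap rules to build one map per group."""
    if not 0 <= include_pct <= edge_pct <= cap_pct:
        raise ConfigurationError(
            f"thresholds must satisfy 0 ≤ include ≤ edge ≤ cap, "
            f"got {include_pct}, {edge_pct}, {cap_pct}"
        )
    thresholds = {"include_pct": include_pct, "edge_pct": edge_pct, "cap_pct": cap_pct,
                  "thickness_scaling": "linear, capped"}
    maps: dict[str, ConnectivityMap] = {}
    for st in sorted(stats, key=lambda s: (s.group, s.region_id)):
        cmap = maps.setdefault(st.group, ConnectivityMap(st.group, thresholds=dict(thresholds)))
        pct = st.mean_fraction * 100.0
        if pct > include_pct:
            cmap.nodes.append(
                {
                    "region_id": st.region_id,
                    "mean_fraction": st.mean_fraction,
                    "sem": st.sem,
                    "bubble": st.mean_fraction,
                }
            )
            if pct > edge_pct:
                cmap.edges.append(
                    {
                        "region_id": st.region_id,
                        "strength_pct": pct,
                        "thickness": min(pct, cap_pct) / cap_pct,
                    }
                )
    return [maps[g] for g in sorted(maps)]


def maps_to_json(maps: list[ConnectivityMap], path: str | Path) -> None:
    Path(path).write_text(json.dumps([m.to_dict() for m in maps], indent=2) + "\n")


def maps_to_table(maps: list[ConnectivityMap]) -> pd.DataFrame:
    """Flat CSV form: one row per node, with edge columns null below the edge threshold."""
    rows = []
    for m in maps:
        edges = {e["region_id"]: e for e in m.edges}
        for node in m.nodes:
            e = edges.get(node["region_id"])
            rows.append(
                {
                    "group": m.group,
                    "region_id": node["region_id"],
                    "mean_fraction": node["mean_fraction"],
                    "sem": node["sem"],
                    "bubble": node["bubble"],
                    "has_edge": e is not None,
                    "strength_pct": e["strength_pct"] if e else np.nan,
                    "thickness": e["thickness"] if e else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["group", "region_id", "mean_fraction", "sem", "bubble",
                 "has_edge", "strength_pct", "thickness"],
    )


def plot_maps(maps: list[ConnectivityMap], path: str | Path, region_names: dict[int, str] | None = None) -> None:
    """Minimal static bubble/edge rendering of the maps (one row per group)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    region_names = region_names or {}
    regions = sorted({n["region_id"] for m in maps for n in m.nodes})
    fig, ax = plt.subplots(figsize=(max(4, len(regions) * 0.9), max(2, len(maps) * 1.2)))
    for gi, m in enumerate(maps):
        ax.scatter([-1.5], [gi], s=150, marker="s", color=f"C{gi}")
        ax.annotate(m.group, (-1.5, gi), textcoords="offset points", xytext=(0, 12), ha="center")
        for node in m.nodes:
            xi = regions.index(node["region_id"])
            ax.scatter([xi], [gi], s=3000 * node["bubble"], color=f"C{gi}", alpha=0.6)
        for e in m.edges:
            xi = regions.index(e["region_id"])
            ax.plot([-1.5, xi], [gi, gi], lw=4 * e["thickness"], color=f"C{gi}", alpha=0.5)
    ax.set_xticks(range(len(regions)))
    ax.set_xticklabels([region_names.get(r, str(r)) for r in regions], rotation=45, ha="right")
    ax.set_yticks(range(len(maps)))
    ax.set_yticklabels([m.group for m in maps])
    ax.set_xlim(-2.5, len(regions))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
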