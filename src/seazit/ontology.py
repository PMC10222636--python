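"""Cross-laboratory phenotype harmonization via ontology mapping.

Each laboratory records altered phenotypes under its own terminology; to
compare findings, every recording is mapped to one or more Zebrafish
Phenotype ontology terms, and terms are rolled up into developmental-defect
groups at two levels: *granular* (e.g. pectoral fin defects) nesting inside
*general* (e.g. fin defects).  A few terms (e.g. death) describe no
structural change and carry no defect group.

The bundled mapping table (``data/ontology_map_partial.csv``) is an
illustrative *partial* fixture covering the commonly shared terms and the
known multi-term recordings; real studies supply their complete table in
the same CSV format (``lab,recording,ontology_id,term_label,
granular_group,general_group``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .specificity import CLASS_PRECEDENCE, SubstanceCall

__all__ = [
    "OntologyMap",
    "GroupCall",
    "load_example_map",
    "map_recording",
    "mapping_stats",
    "overlap",
    "collapse_group",
    "collapse_substance_calls",
    "sankey_edges",
    "endpoint_to_recording",
]

MAP_COLUMNS = [
    "lab",
    "recording",
    "ontology_id",
    "term_label",
    "granular_group",
    "general_group",
]


class OntologyMap:
    """The recording -> term -> granular -> general mapping hierarchy.

    Edges recording->term are many-to-many; each term belongs to at most
    one granular group and each granular group nests in exactly one general
    group (validated on construction).
    """

    def __init__(self, table: pd.DataFrame):
        missing = set(MAP_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"mapping table lacks columns: {sorted(missing)}")
        t = table[MAP_COLUMNS].copy()
        for c in ("ontology_id", "granular_group", "general_group"):
            t[c] = t[c].fillna("").astype(str)
        self.table = t.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        t = self.table
        grp = t[t["granular_group"] != ""]
        for term, g in grp.groupby("term_label")["granular_group"]:
            if g.nunique() > 1:
                raise ValueError(
                    f"term {term!r} maps to multiple granular groups: "
                    f"{sorted(g.unique())}"
                )
        for gran, g in grp.groupby("granular_group")["general_group"]:
            if g.nunique() > 1:
                raise ValueError(
                    f"granular group {gran!r} nests in multiple general groups"
                )

    @classmethod
    def from_csv(cls, path) -> "OntologyMap":
        return cls(pd.read_csv(path))

    def labs(self) -> list[str]:
        return sorted(self.table["lab"].unique())

    def sub_map(self, lab: str) -> pd.DataFrame:
        return self.table[self.table["lab"] == lab]


def load_example_map() -> OntologyMap:
    """The bundled partial mapping fixture (main shared terms only)."""
    with resources.files("seazit.data").joinpath(
        "ontology_map_partial.csv"
    ).open() as fh:
        return OntologyMap(pd.read_csv(fh))


def map_recording(
    recording_name: str, omap: OntologyMap, lab: Optional[str] = None
) -> list[str]:
    """Ontology term labels for one recorded phenotype, in table order.

    Raises ``KeyError`` naming the recording when it is absent from the
    (lab-filtered) map.
    """
    t = omap.table if lab is None else omap.sub_map(lab)
    hits = t[t["recording"] == recording_name]
    if len(hits) == 0:
        raise KeyError(f"recording {recording_name!r} is not in the ontology map")
    seen: list[str] = []
    for term in hits["term_label"]:
        if term not in seen:
            seen.append(term)
    return seen


def mapping_stats(
    omap: OntologyMap, lab: str
) -> tuple[int, int, Optional[float]]:
    """(n recordings, n distinct terms, mean terms per recording) for a lab.

    The mean is the exact ratio (reports round it to 2 decimals); an empty
    lab sub-map yields ``(0, 0, None)`` with a warning.
    """
    sub = omap.sub_map(lab)
    n_rec = sub["recording"].nunique()
    n_terms = sub["term_label"].nunique()
    if n_rec == 0:
        warnings.warn(f"lab {lab!r} has no recordings in the map", stacklevel=2)
        return 0, 0, None
    return n_rec, n_terms, n_terms / n_rec


@dataclass
class OverlapResult:
    """Lab-presence matrices for terms and defect groups."""

    term_presence: pd.DataFrame  # terms x labs, bool
    granular_presence: pd.DataFrame
    general_presence: pd.DataFrame

    def fully_shared(self, level: str = "term") -> int:
        df = {
            "term": self.term_presence,
            "granular": self.granular_presence,
            "general": self.general_presence,
        }[level]
        if df.empty:
            return 0
        return int(df.all(axis=1).sum())


def overlap(omap: OntologyMap, labs: Optional[Sequence[str]] = None) -> OverlapResult:
    """Which labs recorded each ontology term / defect group.

    Presence of an item in a lab means at least one of the lab's recordings
    maps to it.  Requires at least two labs; counts are independent of lab
    order and of recording names.
    """
    labs = list(labs) if labs is not None else omap.labs()
    if len(labs) < 2:
        raise ValueError("overlap requires at least two labs")

    def presence(col: str) -> pd.DataFrame:
        t = omap.table[omap.table[col] != ""] if col != "term_label" else omap.table
        items = sorted(t[col].unique())
        mat = pd.DataFrame(False, index=items, columns=labs)
        for lab in labs:
            present = set(t[t["lab"] == lab][col])
            mat.loc[sorted(present & set(items)), lab] = True
        return mat

    return OverlapResult(
        term_presence=presence("term_label"),
        granular_presence=presence("granular_group"),
        general_presence=presence("general_group"),
    )


@dataclass
class GroupCall:
    """Substance-level call collapsed into one developmental-defect group."""

    substance_id: str
    group: str
    level: str  # "granular" | "general"
    cls: str
    bmc: Optional[float]
    score: Optional[float]
    provenance: tuple[str, ...] = ()


def collapse_group(
    calls: Sequence[SubstanceCall], group: str, level: str = "general"
) -> GroupCall:
    """Representative call for one defect group from its member endpoints.

    The highest-precedence class present wins (specific > non-specific >
    inconclusive > non-toxic); ties within that class are resolved to the
    most potent (numerically smallest log10) BMC.
    """
    if not calls:
        raise ValueError("collapse_group requires at least one contributing call")
    subs = {c.substance_id for c in calls}
    if len(subs) != 1:
        raise ValueError("collapse_group mixes substances")
    for cls in CLASS_PRECEDENCE:
        members = [c for c in calls if c.cls == cls]
        if members:
            with_bmc = [c for c in members if c.bmc_summary is not None]
            if with_bmc:
                best = min(with_bmc, key=lambda c: c.bmc_summary)
            else:
                best = members[0]
            return GroupCall(
                substance_id=best.substance_id,
                group=group,
                level=level,
                cls=cls,
                bmc=best.bmc_summary,
                score=best.score_summary,
                provenance=tuple(c.endpoint for c in members),
            )
    raise ValueError("calls carry no recognised class")  # pragma: no cover


def endpoint_to_recording(endpoint: str) -> str:
    """Recording name behind a combined endpoint label."""
    return endpoint.removesuffix("+Mort@120")


def collapse_substance_calls(
    calls: Sequence[SubstanceCall],
    omap: OntologyMap,
    lab: str,
    level: str = "general",
) -> list[GroupCall]:
    """Collapse endpoint-level substance calls into defect-group calls.

    Each combined endpoint is traced through its recording's ontology terms
    to the requested group level; calls landing in the same substance x
    group are reduced with :func:`collapse_group`.  Endpoints whose
    recording is absent from the map, and terms without a defect group,
    are skipped.
    """
    col = {"granular": "granular_group", "general": "general_group"}[level]
    sub = omap.sub_map(lab)
    buckets: dict[tuple[str, str], list[SubstanceCall]] = {}
    for call in calls:
        rec = endpoint_to_recording(call.endpoint)
        groups = set(sub[sub["recording"] == rec][col]) - {""}
        for g in groups:
            buckets.setdefault((call.substance_id, g), []).append(call)
    return [
        collapse_group(members, group=g, level=level)
        for (s, g), members in sorted(buckets.items())
    ]


def sankey_edges(omap: OntologyMap) -> dict:
    """Flow edges and node annotations of the mapping hierarchy.

    Edges run recording -> term -> granular group -> general group with
    flow counts; node annotations carry: per recording the number of mapped
    terms, per term the number of labs recording it, per group the number
    of recorded phenotypes (across all labs) reaching it.  Terms without a
    defect group emit no outgoing group edge.
    """
    t = omap.table
    edges: list[dict] = []
    rec_term = (
        t.groupby(["lab", "recording", "term_label"]).size().reset_index(name="count")
    )
    for _, row in rec_term.iterrows():
        edges.append(
            {
                "source": f"{row['lab']}:{row['recording']}",
                "target": row["term_label"],
                "kind": "recording->term",
                "count": int(row["count"]),
            }
        )
    grouped = t[t["granular_group"] != ""]
    for (term, gran), g in grouped.groupby(["term_label", "granular_group"]):
        edges.append(
            {
                "source": term,
                "target": gran,
                "kind": "term->granular",
                "count": int(len(g)),
            }
        )
    for (gran, gen), g in grouped.groupby(["granular_group", "general_group"]):
        edges.append(
            {
                "source": gran,
                "target": gen,
                "kind": "granular->general",
                "count": int(len(g)),
            }
        )

    nodes: dict[str, dict] = {}
    for (lab, rec), g in t.groupby(["lab", "recording"]):
        nodes[f"{lab}:{rec}"] = {
            "type": "recording",
            "lab": lab,
            "n_terms": int(g["term_label"].nunique()),
        }
    for term, g in t.groupby("term_label"):
        nodes[term] = {"type": "term", "n_labs": int(g["lab"].nunique())}
    for gran, g in grouped.groupby("granular_group"):
        nodes[gran] = {
            "type": "granular",
            "n_recordings": int(
                g.groupby(["lab", "recording"]).ngroups
            ),
        }
    for gen, g in grouped.groupby("general_group"):
        nodes[gen] = {
            "type": "general",
            "n_recordings": int(g.groupby(["lab", "recording"]).ngroups),
        }
    return {"edges": edges, "nodes": nodes}
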