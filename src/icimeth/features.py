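"""Cross-tumor-type direction-consistent probe voting and feature assembly.

For each responsiveness indicator (OS, TMB, PD-L1), differentially
methylated probes between the two infiltration clusters are computed per
tumor type; a probe becomes a feature for that indicator when it is a DMP
with the SAME direction in at least half of the indicator's significant
tumor types. The three indicator sets are merged, and the immune-signature
probes with a positive beta value in at least one case are added, yielding
the final feature set.

Direction convention: +1 means higher M-value in cluster 2 (the
longer-survival cluster); it is recorded per probe in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from icimeth.diffstats import DifferentialResult, call_dmps


@dataclass
class FeatureSet:
    """Selected probe IDs with per-indicator provenance.

    ``table`` is indexed by probe with columns: direction (+1/-1 for voted
    probes, 0 for signature-only probes), indicators (comma-joined subset of
    OS/TMB/PDL1/signature), vote_count (max over indicators), eligible_types
    (significant-type count of the indicator behind vote_count).
    """

    table: pd.DataFrame

    @property
    def probes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def _tally(
    dmps_by_type: Mapping[str, set[tuple[str, int]]], types: list[str]
) -> dict[tuple[str, int], int]:
    votes: dict[tuple[str, int], int] = {}
    for tt in types:
        for probe, direction in dmps_by_type.get(tt, set()):
            votes[(probe, direction)] = votes.get((probe, direction), 0) + 1
    return votes


def vote_probes_table(
    dmps_by_type: Mapping[str, set[tuple[str, int]]],
    significant_types: Iterable[str],
) -> pd.DataFrame:
    """Direction-consistency vote with per-probe counts.

    A probe is selected with direction d when it is a DMP with direction d
    in at least ceil(K/2) of the K significant tumor types ("half or more",
    so exact halves count for even K). A probe reaching the threshold in
    both directions (possible only at exactly half/half for even K) is
    direction-inconsistent and excluded. Returns a DataFrame indexed by
    probe with columns direction, vote_count, eligible_types.
    """
    types = list(significant_types)
    if not types:
        raise ValueError("no significant tumor types to vote over")
    threshold = math.ceil(len(types) / 2)
    votes = _tally(dmps_by_type, types)

    selected = {key: n for key, n in votes.items() if n >= threshold}
    probes_by_dir: dict[str, list[int]] = {}
    for probe, direction in selected:
        probes_by_dir.setdefault(probe, []).append(direction)
    rows = {
        probe: {
            "direction": dirs[0],
            "vote_count": selected[(probe, dirs[0])],
            "eligible_types": len(types),
        }
        for probe, dirs in probes_by_dir.items()
        if len(dirs) == 1  # drop both-direction conflicts
    }
    if not rows:
        table = pd.DataFrame(columns=["direction", "vote_count", "eligible_types"])
    else:
        table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "probe"
    return table


def vote_probes(
    dmps_by_type: Mapping[str, set[tuple[str, int]]],
    significant_types: Iterable[str],
) -> set[tuple[str, int]]:
    """Set view of :func:`vote_probes_table`: {(probe, direction), ...}."""
    table = vote_probes_table(dmps_by_type, significant_types)
    return {(p, int(d)) for p, d in table["direction"].items()}


def dmps_per_type(
    results_by_type: Mapping[str, DifferentialResult],
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.01,
) -> dict[str, set[tuple[str, int]]]:
    """Apply the DMP calling rule to each tumor type's differential result."""
    return {
        tt: call_dmps(res, lfc_threshold, p_threshold)
        for tt, res in results_by_type.items()
    }


def assemble_feature_set(
    per_indicator_tables: Mapping[str, pd.DataFrame],
    signature_probes: Iterable[str],
    beta: pd.DataFrame,
) -> FeatureSet:
    """Union the voted indicator sets and the usable signature probes.

    ``per_indicator_tables`` maps indicator name to the output of
    :func:`vote_probes_table` (a plain set of (probe, direction) pairs is
    also accepted). Signature probes qualify when they have a positive beta
    value in at least one case. A probe selected by several indicators
    appears once, carrying all its provenances.
    """
    rows: dict[str, dict] = {}
    for indicator, tab in per_indicator_tables.items():
        if isinstance(tab, set):
            tab = pd.DataFrame(
                {"direction": dict(tab)}
            ).rename_axis("probe").assign(vote_count=0, eligible_types=0)
        for probe, rec in tab.iterrows():
            row = rows.setdefault(
                probe,
                {"direction": int(rec["direction"]), "indicators": [],
                 "vote_count": 0, "eligible_types": 0},
            )
            row["indicators"].append(indicator)
            if rec["vote_count"] > row["vote_count"]:
                row["vote_count"] = int(rec["vote_count"])
                row["eligible_types"] = int(rec["eligible_types"])

    present = beta.index.intersection(pd.Index(signature_probes))
    usable = present[(beta.loc[present] > 0).any(axis=1)]
    for probe in usable:
        row = rows.setdefault(
            probe, {"direction": 0, "indicators": [], "vote_count": 0,
                    "eligible_types": 0},
        )
        row["indicators"].append("signature")

    if not rows:
        raise ValueError("empty feature set")
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "probe"
    table["indicators"] = table["indicators"].map(lambda xs: ",".join(sorted(set(xs))))
    return FeatureSet(table=table)
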