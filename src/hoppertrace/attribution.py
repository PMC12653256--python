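"""CI-overlap grouping and destination-source congruence matching.

Two populations are declared significantly different in susceptibility
when their 95% confidence intervals for LC50 do not overlap (an
alpha = 0.05 screen, no multiplicity correction).  The pairwise overlap
matrix is summarised as a compact letter display (CLD): populations
sharing no letter differ significantly.  Destination populations are
grouped from the CLD, each group's member intervals are pooled
(min lower, max upper), and a candidate source region is attributed to
a group when its intervals are statistically indistinguishable from
every member of the group -- by default for both insecticides
(``both_all``), the conjunctive rule that reproduces the reported
field congruence.

Letters are recomputed from the intervals, never trusted from printed
tables; where a printed letter disagrees with strict CI overlap the
pair is surfaced in a discrepancy report rather than reconciled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "SusceptibilityInterval",
    "GroupAssignment",
    "AttributionResult",
    "ci_overlap",
    "compact_letter_display",
    "pooled_interval",
    "match_sources",
    "destination_groups",
    "letter_discrepancies",
    "intervals_from_frame",
]

MATCH_RULES = ("both_all", "either_all", "both_pooled")


@dataclass(frozen=True)
class SusceptibilityInterval:
    """A population's LC50 point estimate and 95% CI for one insecticide."""

    population_id: str
    insecticide: str
    lc50: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower < self.lc50 < self.upper):
            raise ValueError(
                f"{self.population_id}/{self.insecticide}: need lower < lc50 < upper, "
                f"got ({self.lower}, {self.lc50}, {self.upper})"
            )


@dataclass
class GroupAssignment:
    """Compact letter display: population -> letters, letter -> roster."""

    letters: dict  # population_id -> string of letters, e.g. "bc"
    classes: list  # [(letter, [population_id, ...] ascending by LC50)]

    def rosters(self) -> list:
        return [set(members) for _, members in self.classes]


@dataclass
class AttributionResult:
    """Outcome of destination-group <-> candidate-source matching."""

    rule: str
    groups: dict  # group label -> [destination population ids]
    pooled: dict  # (group label, insecticide) -> (lower, upper)
    matches: dict  # group label -> sorted [source ids]
    unmatched_sources: list
    decisions: pd.DataFrame  # one row per (source, group, insecticide, member) test


def ci_overlap(a: SusceptibilityInterval, b: SusceptibilityInterval) -> bool:
    """True iff the two 95% CIs intersect (closed intervals).

    Non-overlap is the significance criterion; the test is symmetric.
    """
    if a.insecticide != b.insecticide:
        raise ValueError(
            f"cannot compare intervals for {a.insecticide!r} and {b.insecticide!r}"
        )
    return max(a.lower, b.lower) <= min(a.upper, b.upper)


def _absorb(classes: list[frozenset]) -> list[frozenset]:
    """Drop letter classes that are subsets of another class."""
    out = []
    for cls in classes:
        if any(cls < other for other in classes):
            continue
        if cls not in out:
            out.append(cls)
    return out


def compact_letter_display(intervals: list[SusceptibilityInterval]) -> GroupAssignment:
    """Insertion-absorption CLD from pairwise CI overlap.

    Populations are processed in ascending LC50 order, so letter naming
    is deterministic: 'a' is the class containing the most susceptible
    populations.  Guarantees: a significantly different pair never
    shares a letter; a non-different pair always shares at least one.
    """
    if len({iv.insecticide for iv in intervals}) > 1:
        raise ValueError("compact_letter_display expects a single insecticide")
    if len({iv.population_id for iv in intervals}) != len(intervals):
        raise ValueError("one interval per population required")
    ivs = sorted(intervals, key=lambda iv: iv.lc50)
    ids = [iv.population_id for iv in ivs]
    by_id = {iv.population_id: iv for iv in ivs}
    classes = [frozenset(ids)]
    for a, b in combinations(ivs, 2):
        if ci_overlap(a, b):
            continue
        new: list[frozenset] = []
        for cls in classes:
            if a.population_id in cls and b.population_id in cls:
                new.append(cls - {a.population_id})
                new.append(cls - {b.population_id})
            else:
                new.append(cls)
        classes = _absorb(new)
    # order classes by the smallest member LC50, then name them a, b, c...
    classes.sort(key=lambda cls: min(by_id[p].lc50 for p in cls))
    letters_for = {pid: "" for pid in ids}
    out_classes = []
    for k, cls in enumerate(classes):
        letter = chr(ord("a") + k)
        members = sorted(cls, key=lambda p: by_id[p].lc50)
        out_classes.append((letter, members))
        for pid in members:
            letters_for[pid] += letter
    return GroupAssignment(letters=letters_for, classes=out_classes)


def pooled_interval(member_intervals: list[SusceptibilityInterval]) -> tuple[float, float]:
    """Envelope of member CIs: (min of lowers, max of uppers)."""
    if not member_intervals:
        raise ValueError("pooled_interval requires at least one member")
    return (
        min(iv.lower for iv in member_intervals),
        max(iv.upper for iv in member_intervals),
    )


def intervals_from_frame(df: pd.DataFrame) -> list[SusceptibilityInterval]:
    """Build intervals from a frame with columns population_id (or
    site_id), insecticide, lc50_mg_L (or lc50), ci_lower, ci_upper."""
    pid = "population_id" if "population_id" in df.columns else "site_id"
    lc = "lc50_mg_L" if "lc50_mg_L" in df.columns else "lc50"
    return [
        SusceptibilityInterval(
            population_id=str(r[pid]),
            insecticide=str(r["insecticide"]),
            lc50=float(r[lc]),
            lower=float(r["ci_lower"]),
            upper=float(r["ci_upper"]),
        )
        for _, r in df.iterrows()
    ]


def destination_groups(
    intervals: list[SusceptibilityInterval], labels: str = "ABC"
) -> dict:
    """Partition destination populations into susceptibility groups.

    Runs the CLD per insecticide and requires (i) each population to
    carry exactly one letter and (ii) the partitions for all
    insecticides to agree; the shared partition is then labelled 'A',
    'B', ... in ascending LC50 order.
    """
    by_ins: dict[str, list[SusceptibilityInterval]] = {}
    for iv in intervals:
        by_ins.setdefault(iv.insecticide, []).append(iv)
    partitions = []
    for ins, ivs in by_ins.items():
        cld = compact_letter_display(ivs)
        multi = [p for p, let in cld.letters.items() if len(let) != 1]
        if multi:
            raise ValueError(
                f"CLD for {ins} does not partition the destinations: "
                f"{multi} carry multiple letters"
            )
        partitions.append([members for _, members in cld.classes])
    rosters = [list(map(set, p)) for p in partitions]
    for other in rosters[1:]:
        if sorted(map(sorted, other)) != sorted(map(sorted, rosters[0])):
            raise ValueError(
                "susceptibility groupings disagree between insecticides"
            )
    ordered = partitions[0]
    labels = list(labels) + [f"G{k}" for k in range(len(labels), len(ordered))]
    return {labels[k]: members for k, members in enumerate(ordered)}


def match_sources(
    destinations: list[SusceptibilityInterval],
    groups: dict,
    sources: list[SusceptibilityInterval],
    rule: str = "both_all",
) -> AttributionResult:
    """Attribute destination groups to candidate source populations.

    Parameters
    ----------
    destinations : intervals (both insecticides) for destination sites.
    groups : mapping group label -> member destination ids.
    sources : intervals for candidate sources; every source must carry
        an interval for every insecticide seen in ``destinations``.
    rule : ``both_all`` (default) -- a source matches a group iff for
        *both* insecticides its CI overlaps the CI of *every* member;
        ``either_all`` -- the all-members condition for at least one
        insecticide; ``both_pooled`` -- overlap with the group's pooled
        interval for both insecticides.
    """
    if rule not in MATCH_RULES:
        raise ValueError(f"unknown matching rule {rule!r}; expected one of {MATCH_RULES}")
    insecticides = sorted({iv.insecticide for iv in destinations})
    dest_ix = {(iv.population_id, iv.insecticide): iv for iv in destinations}
    src_ids = sorted({iv.population_id for iv in sources})
    src_ix = {(iv.population_id, iv.insecticide): iv for iv in sources}
    for sid in src_ids:
        for ins in insecticides:
            if (sid, ins) not in src_ix:
                raise KeyError(f"source {sid!r} lacks an interval for {ins!r}")
    pooled = {}
    for label, members in groups.items():
        for ins in insecticides:
            pooled[(label, ins)] = pooled_interval(
                [dest_ix[(m, ins)] for m in members]
            )
    records = []
    matches = {label: [] for label in groups}
    for sid in src_ids:
        for label, members in groups.items():
            per_ins_ok = {}
            for ins in insecticides:
                siv = src_ix[(sid, ins)]
                if rule == "both_pooled":
                    lo, hi = pooled[(label, ins)]
                    ok = max(siv.lower, lo) <= min(siv.upper, hi)
                    records.append(
                        {
                            "source": sid,
                            "group": label,
                            "insecticide": ins,
                            "member": "<pooled>",
                            "overlap": ok,
                        }
                    )
                    per_ins_ok[ins] = ok
                else:
                    oks = []
                    for m in members:
                        ok = ci_overlap(siv, dest_ix[(m, ins)])
                        oks.append(ok)
                        records.append(
                            {
                                "source": sid,
                                "group": label,
                                "insecticide": ins,
                                "member": m,
                                "overlap": ok,
                            }
                        )
                    per_ins_ok[ins] = all(oks)
            if rule == "either_all":
                matched = any(per_ins_ok.values())
            else:
                matched = all(per_ins_ok.values())
            if matched:
                matches[label].append(sid)
    matched_any = {sid for lst in matches.values() for sid in lst}
    return AttributionResult(
        rule=rule,
        groups={k: list(v) for k, v in groups.items()},
        pooled=pooled,
        matches={k: sorted(v) for k, v in matches.items()},
        unmatched_sources=[s for s in src_ids if s not in matched_any],
        decisions=pd.DataFrame(
            records, columns=["source", "group", "insecticide", "member", "overlap"]
        ),
    )


def letter_discrepancies(
    intervals: list[SusceptibilityInterval], printed_letters: dict
) -> pd.DataFrame:
    """Pairs where printed letters contradict strict CI overlap.

    A shared printed letter asserts "not significantly different"; the
    strict criterion is CI overlap.  Every pair where the two disagree
    is reported with both verdicts (in either direction).
    """
    rows = []
    for a, b in combinations(sorted(intervals, key=lambda iv: iv.lc50), 2):
        share = bool(set(printed_letters[a.population_id]) & set(printed_letters[b.population_id]))
        overlap = ci_overlap(a, b)
        if share != overlap:
            rows.append(
                {
                    "insecticide": a.insecticide,
                    "population_a": a.population_id,
                    "population_b": b.population_id,
                    "ci_overlap": overlap,
                    "share_printed_letter": share,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "insecticide",
            "population_a",
            "population_b",
            "ci_overlap",
            "share_printed_letter",
        ],
    )
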