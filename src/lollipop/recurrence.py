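"""Per-gene recurrence aggregation and highlight selection.

Recurrence ("sample frequency") is a distinct-sample count: a sample
contributes at most once to each distinct alteration and at most once to
each residue position, however many times it appears in the input.  The
per-position totals drive lollipop stem heights; the per-alteration counts
drive labels and the highlight cutoff.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .mutation_io import MutationTable

__all__ = [
    "AlterationCount",
    "RecurrenceProfile",
    "HighlightSet",
    "aggregate",
    "select_highlights",
    "preset_thresholds",
    "export_profile",
    "DEFAULT_THRESHOLD_MENU",
]

#: The default highlight-cutoff menu offered to users.
DEFAULT_THRESHOLD_MENU = (1, 2, 3, 4, 5, 10, 15, 20, 25, 30)


@dataclass(frozen=True)
class AlterationCount:
    """Distinct-sample recurrence of one amino-acid alteration."""

    protein_change: str  # normalized label, e.g. "R175H"
    position: int
    mutation_type: str
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class RecurrenceProfile:
    gene_symbol: str
    per_alteration: tuple[AlterationCount, ...]
    per_position: dict[int, int]

    def __bool__(self) -> bool:
        return bool(self.per_alteration)

    def max_count(self) -> int:
        return max((a.n_samples for a in self.per_alteration), default=0)

    def alteration(self, label: str) -> Optional[AlterationCount]:
        for a in self.per_alteration:
            if a.protein_change == label:
                return a
        return None


@dataclass(frozen=True)
class HighlightSet:
    threshold: int
    members: frozenset[str]


def aggregate(table: MutationTable, gene_symbol: str) -> RecurrenceProfile:
    """Aggregate recurrence for one gene (case-insensitive symbol match).

    The mutation type reported for an alteration is the most frequent raw
    type string among its rows, ties broken lexicographically.  An absent
    gene yields an empty profile with a warning, not an error.
    """
    gene_u = gene_symbol.upper()
    rows = [r for r in table.records if r.gene_symbol.upper() == gene_u]
    if not rows:
        warnings.warn(f"gene {gene_symbol!r} not found in table; empty profile")
        return RecurrenceProfile(gene_symbol, (), {})

    # per-alteration distinct samples and type votes
    samples_by_alt: dict[str, set[str]] = {}
    position_of: dict[str, int] = {}
    type_votes: dict[str, dict[str, int]] = {}
    samples_by_pos: dict[int, set[str]] = {}
    for r in rows:
        label = r.change.label
        samples_by_alt.setdefault(label, set()).add(r.sample_id)
        position_of[label] = r.change.position
        votes = type_votes.setdefault(label, {})
        votes[r.mutation_type_raw] = votes.get(r.mutation_type_raw, 0) + 1
        samples_by_pos.setdefault(r.change.position, set()).add(r.sample_id)

    per_alteration = []
    for label in sorted(samples_by_alt, key=lambda l: (position_of[l], l)):
        votes = type_votes[label]
        # majority vote; lexicographic tie-break
        mtype = min(votes, key=lambda t: (-votes[t], t))
        per_alteration.append(
            AlterationCount(
                protein_change=label,
                position=position_of[label],
                mutation_type=mtype,
                n_samples=len(samples_by_alt[label]),
            )
        )
    per_position = {pos: len(s) for pos, s in sorted(samples_by_pos.items())}
    return RecurrenceProfile(gene_symbol, tuple(per_alteration), per_position)


def select_highlights(profile: RecurrenceProfile, threshold: int) -> HighlightSet:
    """Alterations whose distinct-sample count is >= ``threshold``.

    Cutoff 1 therefore highlights every alteration present in the cohort.
    """
    if threshold < 1:
        raise ValueError(f"threshold must be a positive integer, got {threshold}")
    members = frozenset(
        a.protein_change for a in profile.per_alteration if a.n_samples >= threshold
    )
    return HighlightSet(threshold=threshold, members=members)


def preset_thresholds(extra: Sequence[int] = ()) -> tuple[int, ...]:
    """The highlight-cutoff menu: the default presets plus any user additions."""
    menu = list(DEFAULT_THRESHOLD_MENU)
    for t in extra:
        t = int(t)
        if t < 1:
            raise ValueError(f"threshold menu entries must be >= 1, got {t}")
        if t not in menu:
            menu.append(t)
    return tuple(menu)


def export_profile(
    profile: RecurrenceProfile,
    highlights: HighlightSet,
    path: Union[str, Path],
) -> None:
    """Write the diagram's source data as TSV (gene, change, position, type,
    count, highlighted)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene", "protein_change", "position", "mutation_type", "n_samples", "highlighted"]
        )
        for a in profile.per_alteration:
            writer.writerow(
                [
                    profile.gene_symbol,
                    a.protein_change,
                    a.position,
                    a.mutation_type,
                    a.n_samples,
                    str(a.protein_change in highlights.members).lower(),
                ]
            )
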