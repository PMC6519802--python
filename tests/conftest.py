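"""Shared fixtures and independent oracles for the test suite.

The oracles here (pairwise rectangle overlap, brute-force recurrence
recount) are deliberately written from scratch with plain loops so they
stay independent of the implementation paths they check.
"""

from __future__ import annotations

import io
import random

import pytest

from lollipop.domain_source import bundled_fixture_path, load_protein_record
from lollipop.mutation_io import read_mutation_table


# ---------------------------------------------------------------------------
# independent oracles


def rect_intersection_area(a, b):
    """Axis-aligned rectangle intersection, rectangles as (x, y, w, h)."""
    left = max(a[0], b[0])
    right = min(a[0] + a[2], b[0] + b[2])
    top = max(a[1], b[1])
    bottom = min(a[1] + a[3], b[1] + b[3])
    if right <= left or bottom <= top:
        return 0.0
    return (right - left) * (bottom - top)


def overlapping_pairs(boxes):
    """All (i, j) index pairs whose boxes overlap with positive area."""
    pairs = []
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            if rect_intersection_area(boxes[i], boxes[j]) > 0.0:
                pairs.append((i, j))
    return pairs


def brute_force_recount(rows, gene):
    """Recount recurrence directly from raw (gene, sample, label, pos) rows.

    Returns (per_alteration_counts, per_position_counts) as dicts, counting
    each sample at most once per alteration and once per position.
    """
    per_alt = {}
    per_pos = {}
    for g, sample, label, pos in rows:
        if g.upper() != gene.upper():
            continue
        per_alt.setdefault(label, set()).add(sample)
        per_pos.setdefault(pos, set()).add(sample)
    return (
        {k: len(v) for k, v in per_alt.items()},
        {k: len(v) for k, v in per_pos.items()},
    )


def random_cohort_rows(rng: random.Random, n_rows=40, n_samples=8, n_positions=20):
    """Random raw rows for oracle comparisons: (gene, sample, label, position)."""
    aa = "ACDEFGHIKLMNPQRSTVWY"
    rows = []
    for _ in range(n_rows):
        sample = f"S{rng.randint(1, n_samples)}"
        pos = rng.randint(1, n_positions)
        ref = aa[pos % len(aa)]  # ref fixed per position, as in a real protein
        alt = rng.choice([a for a in aa if a != ref])
        rows.append(("GENE1", sample, f"{ref}{pos}{alt}", pos))
    return rows


def rows_to_table(rows):
    """Serialize oracle rows to TSV and read them through the real parser."""
    lines = ["Hugo_Symbol\tSample_ID\tProtein_Change\tMutation_Type"]
    for gene, sample, label, _pos in rows:
        lines.append(f"{gene}\t{sample}\tp.{label}\tMissense_Mutation")
    return read_mutation_table(io.StringIO("\n".join(lines) + "\n"))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def tp53_record():
    return load_protein_record(bundled_fixture_path("TP53"))


@pytest.fixture
def tp53_fixture_path():
    return bundled_fixture_path("TP53")


@pytest.fixture
def demo_table():
    text = (
        "Hugo_Symbol\tSample_ID\tProtein_Change\tMutaiton_Type\n"
        "TP53\tS1\tp.R175H\tMissense_Mutation\n"
        "TP53\tS2\tp.R175H\tMissense_Mutation\n"
        "TP53\tS3\tp.R175H\tMissense_Mutation\n"
        "TP53\tS4\tp.R175L\tMissense_Mutation\n"
        "TP53\tS5\tp.R273*\tNonsense_Mutation\n"
        "EGFR\tS1\tp.L858R\tMissense_Mutation\n"
    )
    return read_mutation_table(io.StringIO(text))


@pytest.fixture
def no_network(monkeypatch):
    """Make any urllib network attempt an immediate test failure."""
    import urllib.request

    def _fail(*args, **kwargs):
        raise AssertionError("network access attempted in offline test")

    monkeypatch.setattr(urllib.request, "urlopen", _fail)
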