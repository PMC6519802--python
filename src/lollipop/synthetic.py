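"""Seeded synthetic cohort generator for demos and network-free tests.

Emulates the shape of a sequenced cancer cohort's mutation table: a few
recurrent hotspot alterations carried by fixed fractions of samples, on
top of a low-rate background of unique passenger mutations scattered
uniformly along the protein.  Hotspot carrier counts are constructed
exactly (``round(fraction * n_samples)`` distinct samples), so aggregation
recovers them without sampling noise; the background is Poisson per
sample.  Identical seeds produce byte-identical files.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

__all__ = ["Hotspot", "SyntheticCohortSpec", "generate_synthetic_cohort"]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Hotspot:
    position: int
    fraction: float  # of samples carrying this exact alteration
    alteration: Optional[str] = None  # e.g. "R175H"; derived from seed if None
    mutation_type: str = "Missense_Mutation"

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("hotspot fraction must be in [0, 1]")
        if self.position < 1:
            raise ValueError("hotspot position must be >= 1")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n_samples: int = 50
    gene_symbol: str = "TP53"
    protein_length: int = 393
    hotspots: tuple[Hotspot, ...] = (
        Hotspot(175, 0.24, "R175H"),
        Hotspot(273, 0.16, "R273C"),
        Hotspot(273, 0.08, "R273H"),
        Hotspot(245, 0.10, "G245S"),
        Hotspot(213, 0.06, "R213*", "Nonsense_Mutation"),
    )
    background_mutation_rate: float = 0.8  # mean passenger mutations per sample
    mutation_type_mix: tuple[tuple[str, float], ...] = (
        ("Missense_Mutation", 0.70),
        ("Nonsense_Mutation", 0.15),
        ("Frame_Shift_Del", 0.15),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for h in self.hotspots:
            if h.position > self.protein_length:
                raise ValueError(
                    f"hotspot position {h.position} exceeds protein length"
                )
        for _, p in self.mutation_type_mix:
            if not (0.0 <= p <= 1.0):
                raise ValueError("mutation_type_mix proportions must be in [0, 1]")


def _poisson(rng: random.Random, lam: float) -> int:
    """Knuth's method; lam is small (per-sample background rate)."""
    if lam <= 0:
        return 0
    threshold = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= threshold:
            return k
        k += 1


def _hotspot_label(rng: random.Random, h: Hotspot) -> str:
    if h.alteration is not None:
        return h.alteration
    ref = rng.choice(_AA)
    alt = rng.choice([a for a in _AA if a != ref])
    return f"{ref}{h.position}{alt}"


def _pick_type(rng: random.Random, mix: Sequence[tuple[str, float]]) -> str:
    total = sum(p for _, p in mix) or 1.0
    u = rng.random() * total
    acc = 0.0
    for name, p in mix:
        acc += p
        if u <= acc:
            return name
    return mix[-1][0]


def generate_synthetic_cohort(
    spec: SyntheticCohortSpec, path: Union[str, Path]
) -> Path:
    """Write a four-column tab-delimited mutation table; return its path."""
    rng = random.Random(spec.seed)
    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    hotspot_positions = {h.position for h in spec.hotspots}
    rows: list[tuple[str, str, str, str]] = []

    for h in spec.hotspots:
        label = _hotspot_label(rng, h)
        n_carriers = round(h.fraction * spec.n_samples)
        carriers = rng.sample(sample_ids, n_carriers)
        for s in sorted(carriers):
            rows.append((spec.gene_symbol, s, f"p.{label}", h.mutation_type))

    # passengers avoid hotspot positions so constructed counts stay exact
    bg_positions = [
        p for p in range(1, spec.protein_length + 1) if p not in hotspot_positions
    ]
    for s in sample_ids:
        for _ in range(_poisson(rng, spec.background_mutation_rate)):
            if not bg_positions:
                break
            pos = rng.choice(bg_positions)
            mtype = _pick_type(rng, spec.mutation_type_mix)
            ref = rng.choice(_AA)
            if mtype.startswith("Nonsense"):
                label = f"{ref}{pos}*"
            elif mtype.startswith("Frame_Shift"):
                label = f"{ref}{pos}fs"
            else:
                alt = rng.choice([a for a in _AA if a != ref])
                label = f"{ref}{pos}{alt}"
            rows.append((spec.gene_symbol, s, f"p.{label}", mtype))

    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("Hugo_Symbol\tSample_ID\tProtein_Change\tMutation_Type\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return path
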