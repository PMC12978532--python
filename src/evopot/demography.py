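"""Demographic trajectories, decline arithmetic, carrying-capacity scenarios.

A :class:`DemographicTrajectory` is a per-generation effective-size series
with generation 0 at the present and negative indices in the past — the
shape produced by recent-history inference tools (GONE-style two-column
output) and consumed by the forward simulator.  Scenario construction sets
future carrying capacity K to a fraction of the current Ne.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class DemographicTrajectory:
    """Ordered (generation, Ne) pairs; generation 0 = present, negative = past."""

    generations: np.ndarray
    ne: np.ndarray

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=int)
        self.ne = np.asarray(self.ne, dtype=float)
        if self.generations.shape != self.ne.shape:
            raise ValueError("generations and ne must have equal length")
        if not np.all(np.diff(self.generations) > 0):
            raise ValueError("generations must be strictly increasing")
        if np.any(self.ne <= 0):
            raise ValueError("Ne must be strictly positive")

    def __len__(self) -> int:
        return len(self.generations)

    @property
    def current_ne(self) -> float:
        """Ne at generation 0 (the present)."""
        idx = np.flatnonzero(self.generations == 0)
        if idx.size == 0:
            raise ValueError("trajectory has no generation-0 entry")
        return float(self.ne[idx[0]])

    def ne_at(self, generation: int) -> float:
        idx = np.flatnonzero(self.generations == generation)
        if idx.size == 0:
            raise KeyError(f"generation {generation} not in trajectory")
        return float(self.ne[idx[0]])

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["generation\tne"] + [
            f"{g}\t{n:.10g}" for g, n in zip(self.generations, self.ne)
        ]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DemographicTrajectory":
        """Parse a two-column (generation, Ne) table.

        Accepts the GONE output dialect: comment/banner lines and a header
        are skipped; generations listed as positive "generations ago" are
        negated so that 0 is the present.
        """
        gens: list[float] = []
        nes: list[float] = []
        for line in Path(path).read_text().splitlines():
            parts = line.strip().split()
            if len(parts) < 2:
                continue
            try:
                g, n = float(parts[0]), float(parts[1])
            except ValueError:
                continue  # header or banner line
            gens.append(g)
            nes.append(n)
        if not gens:
            raise ValueError(f"no (generation, Ne) rows in {path}")
        garr = np.array(gens)
        if np.all(garr >= 0) and np.any(garr > 0):
            garr = -garr  # "generations ago" convention
        order = np.argsort(garr)
        return cls(garr[order].astype(int), np.array(nes)[order])


@dataclass
class KScenario:
    """Future carrying capacity as a fraction of current Ne."""

    fraction: float
    k: int
    horizon_generations: int = 1000

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("carrying capacity below 2 is not viable")


def decline_percent(n_start: float, n_end: float) -> float:
    """Percent decline from ``n_start`` to ``n_end``: 100 x (1 - end/start).

    Reported to one decimal place, the convention used for census and Ne
    contractions.
    """
    if n_start <= 0:
        raise ValueError("n_start must be positive")
    return round(100.0 * (1.0 - n_end / n_start), 1)


def percent_change(series_start: float, series_end: float, direction: str) -> float:
    """Percent decline or increase between two values of a series.

    ``decline`` is ``100 (1 - end/start)``; ``increase`` is
    ``100 (end - start)/start``.  A zero denominator (an index starting at
    exactly 0, e.g. an inbreeding coefficient anchored at 0) is undefined.
    """
    if direction not in {"decline", "increase"}:
        raise ValueError("direction must be 'decline' or 'increase'")
    if series_start == 0:
        raise ZeroDivisionError(
            "percent change undefined for a series starting at 0"
        )
    if direction == "decline":
        return 100.0 * (1.0 - series_end / series_start)
    return 100.0 * (series_end - series_start) / series_start


def build_k_scenarios(
    current_ne: float,
    fractions: list[float] = (1.0, 0.5, 0.25),
    horizon_generations: int = 1000,
) -> list[KScenario]:
    """One :class:`KScenario` per fraction; K = round(fraction x current Ne).

    Rounding is round-half-up to the nearest integer with a floor of 2
    (a sexual population needs at least one pair).
    """
    if current_ne < 8:
        raise ValueError("current Ne too small to build scenarios")
    out = []
    for f in fractions:
        if f <= 0:
            raise ValueError(f"fraction must be positive, got {f}")
        k = max(2, int(np.floor(f * current_ne + 0.5)))
        out.append(KScenario(fraction=f, k=k, horizon_generations=horizon_generations))
    return out
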