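"""Rank-stability randomization of the across-species body-size order.

How much does the body-size rank order of species depend on which reported
maximum is chosen for each species?  Each randomization draws one report
uniformly from every species' recorded maxima and ranks the species by the
drawn size (ascending, ties averaged).  Pairs of independent rankings are
then compared by Spearman correlation and by the per-species absolute rank
displacement, and the species moving furthest in each pair is recorded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .trait_table import MeasurementRecord

__all__ = ["RankStabilityResult", "measurements_by_species", "draw_ranking", "rank_stability", "top_movers"]


@dataclass
class RankStabilityResult:
    """Per-pair rank correlations and displacement summaries."""

    n_pairs: int
    seed: int
    species_ids: tuple[int, ...]
    rhos: np.ndarray  # per-pair Spearman rho
    median_displacements: np.ndarray  # per-pair median |rank change|
    max_displacements: np.ndarray  # per-pair max |rank change|
    largest_movers: np.ndarray  # per-pair species id attaining the max
    mean_abs_displacement: dict[int, float]  # per species, averaged over pairs

    @property
    def mean_rho(self) -> float:
        return float(self.rhos.mean())

    @property
    def median_of_medians(self) -> float:
        return float(np.median(self.median_displacements))

    @property
    def max_of_maxes(self) -> float:
        return float(self.max_displacements.max())

    def largest_mover_counts(self) -> Counter:
        return Counter(int(s) for s in self.largest_movers if s >= 0)

    def summary(self) -> dict:
        top = self.largest_mover_counts().most_common(1)
        return {
            "n_pairs": self.n_pairs,
            "seed": self.seed,
            "n_species": len(self.species_ids),
            "mean_rho": self.mean_rho,
            "median_of_median_displacements": self.median_of_medians,
            "max_displacement": self.max_of_maxes,
            "modal_largest_mover": top[0][0] if top else None,
            "modal_largest_mover_count": top[0][1] if top else 0,
            "rank_convention": "ascending size, ties averaged",
        }


def measurements_by_species(
    records: Sequence[MeasurementRecord],
) -> dict[int, list[float]]:
    """Group report sizes (cm) by species, duplicates retained."""
    out: dict[int, list[float]] = {}
    for r in records:
        out.setdefault(r.aphia_id, []).append(r.size_cm)
    return out


def _flatten(
    measurements: Mapping[int, Sequence[float]],
    species_order: Sequence[int],
    distinct_only: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ragged per-species report lists as (flat values, offsets, lengths)."""
    lists = []
    for sp in species_order:
        sizes = measurements[sp]
        if len(sizes) == 0:
            raise ValueError(f"species {sp} has no measurements")
        lists.append(sorted(set(sizes)) if distinct_only else list(sizes))
    lens = np.array([len(v) for v in lists])
    offsets = np.concatenate([[0], np.cumsum(lens[:-1])])
    flat = np.concatenate([np.asarray(v, dtype=float) for v in lists])
    return flat, offsets, lens


def _draw_from_flat(flat, offsets, lens, rng) -> np.ndarray:
    drawn = flat[offsets + rng.integers(0, lens)]
    return stats.rankdata(drawn, method="average")


def draw_ranking(
    measurements: Mapping[int, Sequence[float]],
    rng: np.random.Generator,
    species_order: Sequence[int] | None = None,
    distinct_only: bool = False,
) -> np.ndarray:
    """Rank species by one size drawn uniformly from each species' reports.

    Duplicated identical reports are included in the draw by default (they
    encode how often a value is reported); ``distinct_only`` draws over the
    set of distinct values instead.  Returns average ranks, ascending in size,
    aligned with ``species_order`` (default: sorted species ids).
    """
    if species_order is None:
        species_order = sorted(measurements)
    flat, offsets, lens = _flatten(measurements, species_order, distinct_only)
    return _draw_from_flat(flat, offsets, lens, rng)


def rank_stability(
    measurements: Mapping[int, Sequence[float]],
    n_pairs: int = 1000,
    seed: int = 0,
    distinct_only: bool = False,
) -> RankStabilityResult:
    """Draw ``n_pairs`` independent ranking pairs and summarise their agreement.

    For each pair: Spearman correlation between the two rank vectors, the
    median and maximum absolute rank change across species, and the species
    attaining the maximum (ties broken by species id for determinism).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    species = sorted(measurements)
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    ids = np.array(species)
    flat, offsets, lens = _flatten(measurements, species, distinct_only)

    rhos = np.empty(n_pairs)
    med_disp = np.empty(n_pairs)
    max_disp = np.empty(n_pairs)
    movers = np.empty(n_pairs, dtype=int)
    total_disp = np.zeros(len(species))

    for p in range(n_pairs):
        r1 = _draw_from_flat(flat, offsets, lens, rng)
        r2 = _draw_from_flat(flat, offsets, lens, rng)
        # Spearman rho = Pearson correlation of the two rank vectors
        s1, s2 = r1 - r1.mean(), r2 - r2.mean()
        denom = np.sqrt((s1 @ s1) * (s2 @ s2))
        rhos[p] = (s1 @ s2) / denom if denom > 0 else 1.0
        d = np.abs(r1 - r2)
        med_disp[p] = np.median(d)
        max_disp[p] = d.max()
        # -1 marks a pair in which nothing moved; argmax breaks ties by lowest id
        movers[p] = ids[int(np.argmax(d))] if d.max() > 0 else -1
        total_disp += d

    return RankStabilityResult(
        n_pairs=n_pairs,
        seed=seed,
        species_ids=tuple(species),
        rhos=rhos,
        median_displacements=med_disp,
        max_displacements=max_disp,
        largest_movers=movers,
        mean_abs_displacement={sp: float(t / n_pairs) for sp, t in zip(species, total_disp)},
    )


def top_movers(result: RankStabilityResult, k: int = 10) -> list[tuple[int, int, float]]:
    """Species most often the pair's largest mover.

    Returns up to k tuples (species id, times largest mover, mean absolute
    displacement), sorted by count then mean displacement, both descending.
    Species that never move (zero mean displacement and never the largest
    mover) are excluded.
    """
    counts = result.largest_mover_counts()
    rows = [
        (sp, counts.get(sp, 0), result.mean_abs_displacement[sp])
        for sp in result.species_ids
        if counts.get(sp, 0) > 0 or result.mean_abs_displacement[sp] > 0
    ]
    rows.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return rows[:k]
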