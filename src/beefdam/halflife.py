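"""Weight-of-evidence pooling of literature PFOS half-life values.

Published elimination half-lives for PFOS in cattle differ by tissue,
dosing route and study duration.  Each literature value is weighted for its
relevance to long-term dietary exposure with residues in muscle: four
categorical factors (exposure pattern, ingestion type, tissue sampled,
study duration), each 1 or 3, multiplied together and divided by a
per-study divisor that limits the contribution of studies reporting several
tissues.  The pooled distribution draws ``100 x total_weight`` points from a
normal distribution for each evidence row and concatenates them; its sample
mean and SD become the half-life parameter of the accumulation model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HalfLifeEvidence",
    "CombinedHalfLife",
    "DEFAULT_EVIDENCE",
    "total_weight",
    "combine",
]

#: Default SD, as a fraction of the half-life, for rows reported without one.
DEFAULT_SD_FRACTION = 0.20


@dataclass(frozen=True)
class HalfLifeEvidence:
    """One literature half-life value and its weighting attributes.

    Weights: ``exposure_weight`` (1 single bolus, 3 daily), ``type_weight``
    (1 water, 3 food), ``tissue_weight`` (1 blood, 3 muscle/whole body),
    ``duration_weight`` (1 acute, 3 chronic).  ``divisor`` splits the weight
    of studies contributing multiple tissues.
    """

    study_label: str
    tissue: str
    half_life: float  # days
    sd: float | None = None  # days; None -> 20% of half_life
    exposure_weight: int = 1
    type_weight: int = 1
    tissue_weight: int = 1
    duration_weight: int = 1
    divisor: float = 1.0

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be non-negative")
        for w in (self.exposure_weight, self.type_weight,
                  self.tissue_weight, self.duration_weight):
            if w not in (1, 3):
                raise ValueError("weight factors must be 1 or 3")
        if self.divisor <= 0:
            raise ValueError("divisor must be positive")

    @property
    def resolved_sd(self) -> float:
        """The row's SD, falling back to 20% of the half-life."""
        return self.sd if self.sd is not None else DEFAULT_SD_FRACTION * self.half_life


@dataclass(frozen=True)
class CombinedHalfLife:
    """The pooled half-life distribution: the concatenated sample points and
    their mean/SD summary (days)."""

    sample_points: np.ndarray
    mean: float
    sd: float

    @property
    def n_points(self) -> int:
        return len(self.sample_points)


def total_weight(ev: HalfLifeEvidence) -> float:
    """Relevance weight of one evidence row:
    exposure x type x tissue x duration / divisor.

    Multiplying by 100 gives the number of points the row contributes to
    the pooled distribution.
    """
    return (
        ev.exposure_weight * ev.type_weight * ev.tissue_weight * ev.duration_weight
        / ev.divisor
    )


def _row_rng(ev: HalfLifeEvidence, seed: int) -> np.random.Generator:
    # Per-row substream keyed on the row's identity so that reordering the
    # evidence list leaves the pooled multiset unchanged.
    key = zlib.crc32(f"{ev.study_label}|{ev.tissue}|{ev.half_life}".encode())
    return np.random.default_rng([seed, key])


def combine(
    evidence: list[HalfLifeEvidence],
    points_per_weight: int = 100,
    seed: int = 0,
) -> CombinedHalfLife:
    """Pool evidence rows into a combined half-life distribution.

    Each row contributes ``round(points_per_weight * total_weight)`` draws
    from ``Normal(half_life, sd)``; non-positive draws are rejected and
    redrawn since a half-life must be positive.  Returns the concatenated
    points with their sample mean and SD.
    """
    if not evidence:
        raise ValueError("evidence must be non-empty")
    chunks = []
    for ev in evidence:
        n = int(round(points_per_weight * total_weight(ev)))
        rng = _row_rng(ev, seed)
        draws = rng.normal(ev.half_life, ev.resolved_sd, size=n)
        while True:
            bad = draws <= 0
            if not bad.any():
                break
            draws[bad] = rng.normal(ev.half_life, ev.resolved_sd, size=int(bad.sum()))
        chunks.append(((ev.study_label, ev.tissue, ev.half_life), draws))
    # concatenate in a canonical order so the pool is independent of the
    # order the evidence rows were supplied in
    points = np.concatenate([d for _, d in sorted(chunks, key=lambda c: c[0])])
    return CombinedHalfLife(
        sample_points=points,
        mean=float(points.mean()),
        sd=float(points.std(ddof=1)),
    )


def expected_pooled_mean(evidence: list[HalfLifeEvidence]) -> float:
    """Weight-averaged mean of the evidence rows: the expectation the pooled
    sample mean converges to as points_per_weight grows."""
    weights = np.array([total_weight(ev) for ev in evidence])
    means = np.array([ev.half_life for ev in evidence])
    return float(np.sum(weights * means) / np.sum(weights))


#: Bundled weight-of-evidence table for PFOS half-life in beef cattle.
DEFAULT_EVIDENCE: tuple[HalfLifeEvidence, ...] = (
    HalfLifeEvidence("lupton2014", "Body", 114.2, 22.84, 1, 3, 3, 1, 1.0),
    HalfLifeEvidence("lupton2022", "Steer Plasma", 120.0, 4.1, 1, 3, 1, 3, 3.0),
    HalfLifeEvidence("lupton2022", "Heifer Plasma", 106.0, 23.1, 1, 3, 1, 3, 3.0),
    HalfLifeEvidence("lupton2022", "Grouped Muscle", 165.0, 33.0, 1, 3, 3, 3, 3.0),
    HalfLifeEvidence("drew2022", "Serum", 74.1, 13.4, 3, 1, 1, 3, 2.0),
    HalfLifeEvidence("drew2022", "Muscle", 77.0, 15.4, 3, 1, 3, 3, 2.0),
)
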