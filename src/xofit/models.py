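"""Model family registry.

Four families are fit: ``gamma`` (single-pathway gamma renewal), ``gs``
(gamma sprinkling, two pathways), ``bf`` (beam-film) and ``bfs`` (beam-film
sprinkling).  "Parameter 1" is the interference strength -- the gamma shape
``nu`` or the beam-film relief distance ``d``; "parameter 2" is the P2
proportion ``p`` (fixed at 0 for single-pathway families).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .beam_film import BeamFilmParams
from .renewal import GammaSprinklingParams

__all__ = ["ModelSpec", "FAMILIES"]

FAMILIES = ("gamma", "gs", "bf", "bfs")


@dataclass(frozen=True)
class ModelSpec:
    """A model family with its parameter values."""

    family: str
    interference: float
    p: float = 0.0
    n_precursors: float = 10.0
    s_max: float | None = None  # beam-film terminal stress (calibrated)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; expected {FAMILIES}"
            )
        if self.family in ("gamma", "bf") and self.p != 0.0:
            raise ValueError(
                f"family {self.family!r} is single-pathway; p must be 0"
            )

    @property
    def two_pathway(self) -> bool:
        return self.family in ("gs", "bfs")

    @property
    def is_gamma(self) -> bool:
        return self.family in ("gamma", "gs")

    def gamma_params(self) -> GammaSprinklingParams:
        if not self.is_gamma:
            raise ValueError(f"{self.family!r} has no gamma parameters")
        return GammaSprinklingParams(nu=self.interference, p=self.p)

    def bf_params(self) -> BeamFilmParams:
        if self.is_gamma:
            raise ValueError(f"{self.family!r} has no beam-film parameters")
        if self.s_max is None:
            raise ValueError(
                "s_max not set; run beam_film.calibrate_stress first"
            )
        return BeamFilmParams(
            d=self.interference,
            p=self.p,
            n_precursors=self.n_precursors,
            s_max=self.s_max,
        )

    def with_params(self, interference: float, p: float) -> "ModelSpec":
        return replace(self, interference=interference, p=p)
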