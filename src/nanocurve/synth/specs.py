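"""Parameter objects and ground truth for the synthetic image generator."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from ..errors import RenderError

#: Recognised channel roles.
ROLES = frozenset(
    {"registration", "membrane", "integrin", "poi", "donor", "acceptor", "fibre", "cell"}
)

#: Roles whose signal lives on the plasma membrane and therefore exists only
#: inside the cell footprint and is subject to per-structure wrapping factors.
MEMBRANE_ROLES = frozenset({"membrane", "integrin", "poi", "donor", "acceptor"})


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of a periodic nanostructure array.

    Defaults follow the fabricated nanobar geometry: 200 nm x 2 um bars at
    5 um pitch, rendered at 0.1 um/pixel.
    """

    pitch_um: float = 5.0
    origin: tuple[float, float] = (25.0, 25.0)  # (x, y) pixels
    orientation_deg: float = 0.0
    structure_kind: str = "bar"  # {"bar", "pillar"}
    bar_length_um: float = 2.0
    bar_width_um: float = 0.2
    pillar_diameter_um: float = 0.5
    pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise RenderError("pixel_size_um must be > 0")
        if not (0.0 <= self.orientation_deg < 180.0):
            raise RenderError("orientation_deg must lie in [0, 180)")
        if self.structure_kind not in ("bar", "pillar"):
            raise RenderError(f"unknown structure_kind {self.structure_kind!r}")
        extent = (
            self.bar_length_um if self.structure_kind == "bar" else self.pillar_diameter_um
        )
        if self.pitch_um <= extent:
            raise RenderError(
                f"pitch ({self.pitch_um} um) must exceed the structure extent ({extent} um)"
            )

    @property
    def pitch_px(self) -> float:
        return self.pitch_um / self.pixel_size_um


@dataclass(frozen=True)
class ChannelSpec:
    """Photometric model of one imaging channel.

    ``end_enrichment`` is the multiplicative factor applied at high-curvature
    sites (bar ends, pillar circumference); 1 means no curvature preference.
    ``flat_level`` is the off-structure membrane signal relative to
    ``base_intensity`` (membrane lying flat carries less projected signal
    than membrane wrapped around a vertical structure).
    """

    role: str
    base_intensity: float = 200.0
    end_enrichment: float = 1.0
    background: float = 10.0
    read_noise_sd: float = 2.0
    flat_level: float = 0.3

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise RenderError(f"unknown channel role {self.role!r}")
        if self.base_intensity < 0 or self.background < 0:
            raise RenderError("intensities must be non-negative")
        if self.end_enrichment < 0:
            raise RenderError("end_enrichment must be >= 0")
        if self.read_noise_sd < 0:
            raise RenderError("read_noise_sd must be >= 0")


@dataclass
class WrapField:
    """Per-structure multiplicative wrapping factors.

    Models uneven membrane wrapping: the same factor multiplies every
    membrane-bound channel at a given structure, so membrane-normalised
    ratios are invariant to it.
    """

    factors: np.ndarray
    end_factors: np.ndarray | None = None  # optional end-specific wrapping

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise RenderError("wrap factors must be > 0")
        if self.end_factors is not None:
            self.end_factors = np.asarray(self.end_factors, dtype=float)
            if self.end_factors.shape != self.factors.shape:
                raise RenderError("end_factors must match factors in shape")
            if np.any(self.end_factors <= 0):
                raise RenderError("wrap factors must be > 0")

    @property
    def at_end(self) -> np.ndarray:
        return self.factors if self.end_factors is None else self.end_factors

    def __len__(self) -> int:
        return len(self.factors)

    @classmethod
    def none(cls, n: int) -> "WrapField":
        return cls(np.ones(n))

    @classmethod
    def uniform(
        cls,
        n: int,
        lo: float = 0.7,
        hi: float = 1.3,
        rng=None,
        uneven_ends: bool = False,
    ) -> "WrapField":
        rng = np.random.default_rng(rng)
        end = rng.uniform(lo, hi, size=n) if uneven_ends else None
        return cls(rng.uniform(lo, hi, size=n), end_factors=end)


@dataclass
class GroundTruth:
    """Hidden parameters of a synthetic render, for recovery tests."""

    lattice: LatticeSpec
    enrichment: Mapping[str, float] = field(default_factory=dict)  # role -> E
    wrap_factors: np.ndarray | None = None
    node_xy: np.ndarray | None = None  # (n, 2) structure centres, pixels
    per_structure_enrichment: Mapping[str, np.ndarray] | None = None
    bar_diameters_um: np.ndarray | None = None  # gradient fields
    enriched_fraction: float | None = None
    rho_true: float | None = None
    traces: np.ndarray | None = None  # (n_structures, n_frames)
    cell_depths_um: np.ndarray | None = None
    seed: int | None = None

    def to_json(self) -> str:
        def convert(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: convert(x) for k, x in v.items()}
            return v

        d = asdict(self)
        d["lattice"] = asdict(self.lattice)
        return json.dumps({k: convert(v) for k, v in d.items()}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        lat = d.pop("lattice")
        lat["origin"] = tuple(lat["origin"])
        gt = cls(lattice=LatticeSpec(**lat))
        for k, v in d.items():
            if v is None:
                continue
            if k in ("wrap_factors", "node_xy", "bar_diameters_um", "traces", "cell_depths_um"):
                v = np.asarray(v, dtype=float)
            elif k == "per_structure_enrichment":
                v = {r: np.asarray(a, dtype=float) for r, a in v.items()}
            setattr(gt, k, v)
        return gt
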