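"""Tissue thermal properties, uncertainty sampling and phantom construction.

The simulated target is a 1-D breast phantom: a superficial fat layer over
glandular tissue, with a small spherical tumour (modelled as an interval on
the depth axis) embedded in the gland.  Each region carries the Pennes-model
parameters: density ``rho``, specific heat ``c``, thermal conductivity ``k``,
the lumped blood-perfusion term ``gc`` (= w_b * c_b, in W/(m^3 C)) and a
metabolic volumetric heat ``qm``.

Nominal values are literature means for fat, gland and tumour tissue; the
blood-dependent parameters are uncertain between individuals, so the module
also provides uniform sampling of properties within configurable closed
intervals (the clinically reported ranges: c in [3000, 4500] J/(kg K),
rho in [800, 1600] kg/m^3, k in [0.2, 0.6] W/(m K), blood temperature in
[36, 39] C, fat perfusion in [800, 1600] and gland perfusion in
[800, 3600] W/(m^3 C)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np

REGIONS = ("fat", "gland", "tumour")

#: Nominal (mean) Pennes parameters per region.  The tumour's metabolic heat
#: is not pinned down by the source tables; 4200 W/m^3 is this package's
#: configurable default (a few times the gland value, typical of tumour
#: hypermetabolism), not a literature mean.
DEFAULT_TUMOUR_QM = 4200.0

_TABLE = {
    "fat": dict(rho=930.0, c=2770.0, k=0.28, gc=800.0, qm=400.0),
    "gland": dict(rho=1050.0, c=3770.0, k=0.48, gc=2400.0, qm=720.0),
    "tumour": dict(rho=1050.0, c=3770.0, k=0.48, gc=48000.0, qm=DEFAULT_TUMOUR_QM),
}


@dataclass(frozen=True)
class TissueProperties:
    """Pennes parameters of one homogeneous tissue region.

    Attributes
    ----------
    rho : float
        Density, kg/m^3.
    c : float
        Specific heat, J/(kg K).
    k : float
        Thermal conductivity, W/(m K).
    gc : float
        Blood perfusion term w_b*c_b, W/(m^3 C).
    qm : float
        Metabolic volumetric heat, W/m^3.
    """

    rho: float
    c: float
    k: float
    gc: float
    qm: float

    def __post_init__(self) -> None:
        for name in ("rho", "c", "k", "gc", "qm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"TissueProperties.{name} must be strictly positive and finite, got {v!r}"
                )


def default_properties(region: str, tumour_qm: float = DEFAULT_TUMOUR_QM) -> TissueProperties:
    """Return the nominal :class:`TissueProperties` for ``region``.

    ``region`` must be one of ``"fat"``, ``"gland"``, ``"tumour"``.  The
    tumour metabolic heat is configurable through ``tumour_qm`` since its
    nominal value is not tabulated alongside the other parameters.
    """
    if region not in _TABLE:
        raise ValueError(f"unknown tissue region {region!r}; expected one of {REGIONS}")
    vals = dict(_TABLE[region])
    if region == "tumour":
        vals["qm"] = float(tumour_qm)
    return TissueProperties(**vals)


@dataclass(frozen=True)
class Interval:
    """Closed interval [lo, hi] for one uncertain parameter."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"interval lower bound {self.lo} exceeds upper bound {self.hi}")

    @property
    def width(self) -> float:
        return self.hi - self.lo


def _fixed(v: float) -> Interval:
    return Interval(v, v)


@dataclass(frozen=True)
class UncertaintyRanges:
    """Per-region closed intervals for the uncertain Pennes parameters.

    Defaults follow the clinically reported ranges: specific heat
    3000-4500, density 800-1600, conductivity 0.2-0.6, blood temperature
    36-39 C, fat perfusion 800-1600 and gland perfusion 800-3600 W/(m^3 C).
    Tumour perfusion and all metabolic heats default to zero-width intervals
    at their nominal values.  Any interval may be replaced, e.g. pinned to a
    point to remove that parameter's uncertainty.
    """

    rho: dict[str, Interval] = field(
        default_factory=lambda: {r: Interval(800.0, 1600.0) for r in REGIONS}
    )
    c: dict[str, Interval] = field(
        default_factory=lambda: {r: Interval(3000.0, 4500.0) for r in REGIONS}
    )
    k: dict[str, Interval] = field(
        default_factory=lambda: {r: Interval(0.2, 0.6) for r in REGIONS}
    )
    gc: dict[str, Interval] = field(
        default_factory=lambda: {
            "fat": Interval(800.0, 1600.0),
            "gland": Interval(800.0, 3600.0),
            "tumour": _fixed(_TABLE["tumour"]["gc"]),
        }
    )
    qm: dict[str, Interval] = field(
        default_factory=lambda: {r: _fixed(_TABLE[r]["qm"]) for r in REGIONS}
    )
    t_b: Interval = field(default_factory=lambda: Interval(36.0, 39.0))

    @classmethod
    def degenerate(cls, tumour_qm: float = DEFAULT_TUMOUR_QM) -> "UncertaintyRanges":
        """Zero-width intervals at the nominal values (sampling returns them)."""
        cols = {r: default_properties(r, tumour_qm) for r in REGIONS}
        return cls(
            rho={r: _fixed(cols[r].rho) for r in REGIONS},
            c={r: _fixed(cols[r].c) for r in REGIONS},
            k={r: _fixed(cols[r].k) for r in REGIONS},
            gc={r: _fixed(cols[r].gc) for r in REGIONS},
            qm={r: _fixed(cols[r].qm) for r in REGIONS},
            t_b=_fixed(37.0),
        )

    @classmethod
    def perfusion_only(cls) -> "UncertaintyRanges":
        """Only fat/gland perfusion uncertain; everything else nominal."""
        base = cls.degenerate()
        gc = dict(base.gc)
        gc["fat"] = Interval(800.0, 1600.0)
        gc["gland"] = Interval(800.0, 3600.0)
        return replace(base, gc=gc)


def sample_uncertain_properties(
    ranges: UncertaintyRanges,
    seed: int | np.random.Generator,
) -> tuple[dict[str, TissueProperties], float]:
    """Draw one random plant: per-region properties plus blood temperature.

    Each parameter is drawn independently and uniformly on its interval.
    The draw order is fixed (region-major, parameter-minor) so an identical
    seed yields a bitwise-identical draw.

    Returns ``(props, t_b)`` where ``props`` maps region name to
    :class:`TissueProperties` and ``t_b`` is the arterial blood temperature
    in C.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    props: dict[str, TissueProperties] = {}
    for region in REGIONS:
        drawn = {}
        for name in ("rho", "c", "k", "gc", "qm"):
            iv: Interval = getattr(ranges, name)[region]
            drawn[name] = float(rng.uniform(iv.lo, iv.hi)) if iv.width > 0 else iv.lo
        props[region] = TissueProperties(**drawn)
    tb_iv = ranges.t_b
    t_b = float(rng.uniform(tb_iv.lo, tb_iv.hi)) if tb_iv.width > 0 else tb_iv.lo
    return props, t_b


@dataclass(frozen=True)
class PhantomGeometry:
    """1-D layered geometry: ``fat | gland`` with a tumour interval inside the gland.

    Depth ``x`` runs from the irradiated skin surface (x = 0) into the body.
    All lengths in metres.
    """

    fat_depth: float = 0.010
    gland_depth: float = 0.040
    tumour_diameter: float = 0.006
    tumour_centre_depth: float = 0.020
    dx: float = 0.25e-3

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError(f"grid spacing dx must be positive, got {self.dx}")
        if self.fat_depth < 0 or self.gland_depth <= 0 or self.tumour_diameter < 0:
            raise ValueError("layer thicknesses must be non-negative (gland positive)")
        r = self.tumour_diameter / 2.0
        if self.tumour_diameter > 0 and not (
            self.fat_depth <= self.tumour_centre_depth - r
            and self.tumour_centre_depth + r <= self.fat_depth + self.gland_depth
        ):
            raise ValueError(
                "tumour interval "
                f"[{self.tumour_centre_depth - r:.4g}, {self.tumour_centre_depth + r:.4g}] m "
                f"extends outside the gland layer [{self.fat_depth:.4g}, "
                f"{self.fat_depth + self.gland_depth:.4g}] m"
            )

    @property
    def length(self) -> float:
        """Total domain length (fat + gland), m."""
        return self.fat_depth + self.gland_depth

    @property
    def tumour_interval(self) -> tuple[float, float]:
        r = self.tumour_diameter / 2.0
        return (self.tumour_centre_depth - r, self.tumour_centre_depth + r)


@dataclass(frozen=True)
class Phantom:
    """A discretised phantom: grid, region labels, properties and blood temperature."""

    x: np.ndarray  # node positions, m
    region: np.ndarray  # region label per node (unicode)
    properties: dict[str, TissueProperties]
    t_b: float = 37.0
    geometry: PhantomGeometry | None = None

    def __post_init__(self) -> None:
        if len(self.x) != len(self.region):
            raise ValueError("node positions and region labels differ in length")
        missing = set(np.unique(self.region)) - set(self.properties)
        if missing:
            raise ValueError(f"no TissueProperties supplied for region(s) {sorted(missing)}")

    @property
    def n_nodes(self) -> int:
        return len(self.x)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    def per_node(self, name: str) -> np.ndarray:
        """Vector of one property (``rho``/``c``/``k``/``gc``/``qm``) over the grid."""
        lut = {r: getattr(p, name) for r, p in self.properties.items()}
        return np.array([lut[r] for r in self.region], dtype=float)

    @property
    def tumour_centre(self) -> float:
        if self.geometry is not None and self.geometry.tumour_diameter > 0:
            return self.geometry.tumour_centre_depth
        mask = self.region == "tumour"
        if not mask.any():
            raise ValueError("phantom has no tumour region")
        return float(self.x[mask].mean())

    def with_properties(
        self, props: dict[str, TissueProperties], t_b: float | None = None
    ) -> "Phantom":
        """Same grid/labels with replaced properties (and optionally blood temperature)."""
        return Phantom(
            x=self.x,
            region=self.region,
            properties=props,
            t_b=self.t_b if t_b is None else float(t_b),
            geometry=self.geometry,
        )

    def to_dict(self) -> dict:
        """JSON/YAML-serialisable description (geometry + properties, not the raw grid)."""
        if self.geometry is None:
            raise ValueError("only geometry-built phantoms are serialisable")
        return {
            "geometry": asdict(self.geometry),
            "properties": {r: asdict(p) for r, p in self.properties.items()},
            "t_b": self.t_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Phantom":
        geom = PhantomGeometry(**d["geometry"])
        props = {r: TissueProperties(**p) for r, p in d["properties"].items()}
        return build_phantom(geom, props, t_b=d.get("t_b", 37.0))


def build_phantom(
    geometry: PhantomGeometry | None = None,
    props: dict[str, TissueProperties] | None = None,
    t_b: float = 37.0,
) -> Phantom:
    """Discretise ``geometry`` onto a uniform grid and label every node.

    A node is labelled ``tumour`` iff its position lies in the closed tumour
    interval [centre - r, centre + r]; otherwise ``fat`` for x <= fat depth
    and ``gland`` beyond.  Node count is ``round(length/dx) + 1``.
    """
    geometry = geometry or PhantomGeometry()
    if props is None:
        props = {r: default_properties(r) for r in REGIONS}
    n = int(round(geometry.length / geometry.dx)) + 1
    x = np.linspace(0.0, geometry.length, n)
    region = np.where(x <= geometry.fat_depth + 1e-12, "fat", "gland").astype(object)
    if geometry.tumour_diameter > 0:
        lo, hi = geometry.tumour_interval
        region[(x >= lo - 1e-12) & (x <= hi + 1e-12)] = "tumour"
    region = region.astype(str)
    used = set(np.unique(region))
    props = {r: p for r, p in props.items() if r in used}
    return Phantom(x=x, region=region, properties=props, t_b=float(t_b), geometry=geometry)
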