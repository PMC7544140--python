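"""Synthetic tooth-pit surfaces and observer studies.

The generator emulates the study design the analyses assume: two carnivore
samples (wolf and dog) of 30 pits each, every pit digitised by three
analysts of differing experience under a common landmark scheme.  A pit is
modelled as a smooth elliptical depression — a half-ellipsoid bowl plus a
small smooth roughness field — whose length and width are drawn from the
published size ranges (length 1.176-4.448 mm, width 0.8382-3.5128 mm) and
whose depth scales with width; dog pits are parameterised deeper than wolf
pits.  Analyst error is an isotropic random direction times a log-normal
magnitude whose median is the analyst's per-landmark noise scale, so the
simulated error distributions are right-skewed like the observed ones.

Coordinate convention: right-handed, mm units, pit opening towards +z,
rim in the z = 0 plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .types import (
    SCHEME_LM17,
    SCHEME_LM5,
    LandmarkConfiguration,
    ObserverDataset,
    UnsupportedSchemeError,
    parse_scheme,
)

#: Published per-landmark median inter-analyst errors (mm), used as the
#: default noise scales so simulated studies reproduce the observed rank
#: ordering of landmark difficulty (LM14 worst, LM5 best).
TABLE_MEDIAN_ERRORS_MM: dict[str, float] = {
    "LM1": 0.282, "LM2": 0.279, "LM3": 0.324, "LM4": 0.342, "LM5": 0.175,
    "LM6": 0.279, "LM7": 0.287, "LM8": 0.315, "LM9": 0.271, "LM10": 0.321,
    "LM11": 0.288, "LM12": 0.339, "LM13": 0.297, "LM14": 0.352,
    "LM15": 0.260, "LM16": 0.278, "LM17": 0.315,
}

#: Noise multipliers by experience rank (1 = least experienced analyst).
EXPERIENCE_FACTORS: dict[int, float] = {1: 1.3, 2: 1.15, 3: 1.0}

#: Median digitisation noise (mm) for computed semilandmark points, which
#: carry far less observer judgement than hand-placed landmarks.
SEMILANDMARK_NOISE_MM = 0.08


class InvalidParameterError(ValueError):
    pass


class InvalidProfileError(ValueError):
    pass


@dataclass(frozen=True)
class PitPopulationParams:
    """Morphological population parameters for one carnivore's pits."""

    carnivore_label: str
    length_range: tuple[float, float] = (1.176, 4.448)
    width_range: tuple[float, float] = (0.8382, 3.5128)
    depth_scale: float = 0.35  # max depth as a fraction of pit width
    depth_to_width_ratio_sd: float = 0.2  # log-normal shape of that fraction
    surface_roughness: float = 0.02  # mm amplitude of the rim-vanishing bump field

    def validate(self) -> None:
        for name, (lo, hi) in (("length_range", self.length_range),
                               ("width_range", self.width_range)):
            if not (0 < lo <= hi):
                raise InvalidParameterError(f"{name} must satisfy 0 < min <= max")
        if self.depth_scale <= 0 or self.depth_to_width_ratio_sd <= 0:
            raise InvalidParameterError("depth parameters must be strictly positive")
        if self.surface_roughness < 0:
            raise InvalidParameterError("surface_roughness must be non-negative")


def wolf_params(**overrides) -> PitPopulationParams:
    """Default wolf pit population: shallow, weak topographic relief."""
    return replace(PitPopulationParams("wolf", depth_scale=0.25), **overrides)


def dog_params(**overrides) -> PitPopulationParams:
    """Default dog pit population: markedly deeper pits."""
    return replace(PitPopulationParams("dog", depth_scale=0.45), **overrides)


@dataclass(frozen=True)
class AnalystProfile:
    """One analyst's noise model: per-landmark median error scales (mm)."""

    analyst_id: str
    experience_rank: int  # 1 = least experienced
    per_landmark_noise_scale: dict[str, float]
    noise_skew: float = 0.6  # log-normal shape parameter of the error magnitude

    def validate(self, labels: Sequence[str]) -> None:
        for lab in labels:
            if lab not in self.per_landmark_noise_scale:
                raise InvalidProfileError(
                    f"analyst {self.analyst_id} has no noise scale for {lab}"
                )
            if self.per_landmark_noise_scale[lab] < 0:
                raise InvalidProfileError("noise scales must be non-negative")

    def scaled(self, factor: float) -> "AnalystProfile":
        return replace(
            self,
            per_landmark_noise_scale={
                k: v * factor for k, v in self.per_landmark_noise_scale.items()
            },
        )


def default_noise_scales(labels: Sequence[str]) -> dict[str, float]:
    """Published medians for LM labels; a small scale for semilandmarks."""
    return {
        lab: TABLE_MEDIAN_ERRORS_MM.get(lab, SEMILANDMARK_NOISE_MM) for lab in labels
    }


def default_analysts(labels: Sequence[str] = SCHEME_LM17) -> list[AnalystProfile]:
    """Three analysts A1-A3 of increasing experience (decreasing noise)."""
    base = default_noise_scales(labels)
    out = []
    for rank in (1, 2, 3):
        factor = EXPERIENCE_FACTORS[rank]
        out.append(
            AnalystProfile(
                analyst_id=f"A{rank}",
                experience_rank=rank,
                per_landmark_noise_scale={k: v * factor for k, v in base.items()},
            )
        )
    return out


@dataclass(frozen=True)
class ObserverStudyConfig:
    """Full design of one simulated observer study."""

    n_pits_per_carnivore: int = 30
    analysts: tuple[AnalystProfile, ...] | None = None  # None -> default A1-3
    landmark_scheme: str = "LM17"
    seed: int = 0
    wolf: PitPopulationParams = field(default_factory=wolf_params)
    dog: PitPopulationParams = field(default_factory=dog_params)

    def validate(self) -> None:
        if self.n_pits_per_carnivore < 1:
            raise InvalidParameterError("n_pits_per_carnivore must be >= 1")
        if self.analysts is not None and len(self.analysts) == 0:
            raise InvalidParameterError("at least one analyst is required")
        parse_scheme(self.landmark_scheme)
        self.wolf.validate()
        self.dog.validate()
        ranks = [a.experience_rank for a in (self.analysts or ())]
        if len(ranks) != len(set(ranks)):
            raise InvalidParameterError("analyst experience ranks must be unique")


@dataclass(frozen=True)
class ParametricPitSurface:
    """A smooth elliptical depression, parameterised on the unit square.

    ``point(u, v)`` maps u to the rim angle (theta = 2 pi u) and v to the
    radial fraction rho, with the rim at rho = 1 (z = 0) and the bowl
    reaching ``-max_depth`` in the interior.  The roughness bump field
    vanishes at both the rim and the centre, so the depth extremum of the
    smooth bowl is preserved for small amplitudes.
    """

    length: float  # full length along x, mm
    width: float   # full width along y, mm
    max_depth: float  # mm, depth of the smooth bowl at the centre
    roughness: float = 0.0  # mm amplitude of the bump field
    bump_waves: int = 3
    bump_phase: float = 0.0

    def _bowl(self, rho: np.ndarray) -> np.ndarray:
        return -self.max_depth * np.sqrt(np.clip(1.0 - rho**2, 0.0, None))

    def _bump(self, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
        if self.roughness == 0.0:
            return np.zeros(np.broadcast(rho, theta).shape)
        envelope = 4.0 * rho**2 * (1.0 - rho**2)  # 0 at centre and rim, max 1
        return self.roughness * np.sin(self.bump_waves * theta + self.bump_phase) * envelope

    def depth(self, rho, theta) -> np.ndarray:
        rho = np.asarray(rho, float)
        theta = np.asarray(theta, float)
        return self._bowl(rho) + self._bump(rho, theta)

    def point(self, u, v) -> np.ndarray:
        """Surface point(s) for parameters (u, v) in the unit square."""
        u = np.asarray(u, float)
        v = np.asarray(v, float)
        theta = 2.0 * np.pi * u
        x = 0.5 * self.length * v * np.cos(theta)
        y = 0.5 * self.width * v * np.sin(theta)
        z = self.depth(v, theta)
        return np.stack([x, y, z], axis=-1)

    def height_at(self, x, y) -> np.ndarray:
        """Surface z at planar position (x, y); 0 outside the rim ellipse."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        rho = np.sqrt((2 * x / self.length) ** 2 + (2 * y / self.width) ** 2)
        theta = np.arctan2(y * self.length, x * self.width)  # parameter angle
        z = self.depth(np.clip(rho, 0.0, 1.0), theta)
        return np.where(rho <= 1.0, z, 0.0)

    def rim_points(self, n: int = 512) -> np.ndarray:
        """n points sampled along the rim (z = 0), ordered by angle."""
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        x = 0.5 * self.length * np.cos(theta)
        y = 0.5 * self.width * np.sin(theta)
        return np.stack([x, y, np.zeros(n)], axis=-1)

    def deepest_point(self, grid: int = 96) -> np.ndarray:
        """Deepest interior surface point (grid search; exact when smooth)."""
        if self.roughness == 0.0:
            return np.array([0.0, 0.0, -self.max_depth])
        u = np.linspace(0.0, 1.0, grid, endpoint=False)
        v = np.linspace(0.0, 1.0, grid)
        uu, vv = np.meshgrid(u, v)
        pts = self.point(uu.ravel(), vv.ravel())
        return pts[np.argmin(pts[:, 2])]


def generate_pit_surface(
    params: PitPopulationParams, rng: np.random.Generator
) -> ParametricPitSurface:
    """Draw one pit surface from a carnivore's population.

    Length is uniform over the configured range; width is uniform over its
    range truncated at the drawn length (pits are longer than wide); max
    depth is ``depth_scale * width`` times a log-normal factor with median 1.
    """
    params.validate()
    length = float(rng.uniform(*params.length_range))
    w_lo, w_hi = params.width_range
    w_hi = min(w_hi, length)
    w_lo = min(w_lo, w_hi)
    width = float(rng.uniform(w_lo, w_hi))
    depth_factor = float(np.exp(params.depth_to_width_ratio_sd * rng.standard_normal()))
    max_depth = params.depth_scale * width * depth_factor
    return ParametricPitSurface(
        length=length,
        width=width,
        max_depth=max_depth,
        roughness=params.surface_roughness,
        bump_waves=int(rng.integers(2, 6)),
        bump_phase=float(rng.uniform(0.0, 2.0 * np.pi)),
    )


def _rim_axes(rim: np.ndarray) -> tuple[int, int, int, int]:
    """Indices of the maximum-length chord endpoints and the maximum-width
    extremes perpendicular to it, by brute force over the rim samples."""
    d2 = np.sum((rim[:, None, :2] - rim[None, :, :2]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    axis = rim[j, :2] - rim[i, :2]
    axis = axis / np.linalg.norm(axis)
    normal = np.array([-axis[1], axis[0]])
    proj = rim[:, :2] @ normal
    return int(i), int(j), int(np.argmax(proj)), int(np.argmin(proj))


def _point_to_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Planar (xy) distance from p to the infinite line through a and b."""
    u = b[:2] - a[:2]
    w = p[:2] - a[:2]
    return float(abs(u[0] * w[1] - u[1] * w[0]) / np.linalg.norm(u))


def true_landmarks(
    surface: ParametricPitSurface, scheme: str = "LM17", rim_samples: int = 256
) -> LandmarkConfiguration:
    """Ground-truth landmark configuration of a pit surface.

    LM1/LM2 terminate the maximum-length rim chord; LM1 is the endpoint
    furthest from the perpendicular maximum-width axis (ties broken towards
    +x, then +y).  LM3/LM4 terminate the maximum-width chord, LM3 on the
    counter-clockwise side of the LM1->LM2 axis.  LM5 is the deepest
    interior point.  For the 17-landmark scheme, LM6-13 are rim points at
    equal arc fractions (1/3, 2/3) between consecutive axis endpoints in
    rim order LM1 -> LM3 -> LM2 -> LM4, and LM14-17 are interior mid-depth
    points along the four half-axis directions.
    """
    if scheme not in ("LM17", "LM5"):
        raise UnsupportedSchemeError(
            f"true_landmarks supports LM17 and LM5, got {scheme!r}"
        )
    rim = surface.rim_points(rim_samples)
    i1, i2, i3, i4 = _rim_axes(rim)
    p, q = rim[i1], rim[i2]
    r, s = rim[i3], rim[i4]
    dp = _point_to_line_distance(p, r, s)
    dq = _point_to_line_distance(q, r, s)
    if abs(dp - dq) < 1e-9:  # symmetric pit: break tie towards +x then +y
        keys = sorted([(p[0], p[1], i1), (q[0], q[1], i2)], reverse=True)
        lm1_idx = keys[0][2]
    else:
        lm1_idx = i1 if dp > dq else i2
    lm2_idx = i2 if lm1_idx == i1 else i1
    lm1, lm2 = rim[lm1_idx], rim[lm2_idx]
    # LM3 on the counter-clockwise side of LM1 -> LM2
    axis = lm2[:2] - lm1[:2]
    cross_r = axis[0] * (r[1] - lm1[1]) - axis[1] * (r[0] - lm1[0])
    if cross_r < 0:
        (i3, i4), (r, s) = (i4, i3), (s, r)
    lm3_idx, lm4_idx = i3, i4
    coords = [lm1, lm2, rim[lm3_idx], rim[lm4_idx], surface.deepest_point()]

    if scheme == "LM17":
        n = rim.shape[0]
        seg = np.linalg.norm(np.diff(rim[np.arange(n + 1) % n, :2], axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])  # arc length at each rim index
        total = cum[-1]

        def arc_pos(idx: int) -> float:
            return cum[idx]

        def rim_at_arc(t: float) -> np.ndarray:
            t = t % total
            k = int(np.searchsorted(cum, t, side="right")) - 1
            k = min(k, n - 1)
            frac = (t - cum[k]) / seg[k]
            a, b = rim[k], rim[(k + 1) % n]
            return a + frac * (b - a)

        # traverse from LM1 in the direction that reaches LM3 before LM4
        s1 = arc_pos(lm1_idx)
        fwd = lambda idx: (arc_pos(idx) - s1) % total
        direction = 1.0 if fwd(lm3_idx) < fwd(lm4_idx) else -1.0

        def offset(idx: int) -> float:
            return (direction * (arc_pos(idx) - s1)) % total

        order = [lm1_idx, lm3_idx, lm2_idx, lm4_idx]
        offsets = [offset(idx) for idx in order] + [total]
        for a_off, b_off in zip(offsets[:-1], offsets[1:]):
            for frac in (1.0 / 3.0, 2.0 / 3.0):
                t = a_off + frac * (b_off - a_off)
                coords.append(rim_at_arc(s1 + direction * t))

        # LM14-17: interior mid-depth points towards LM1, LM2, LM3, LM4
        half_depth = -0.5 * surface.max_depth
        for anchor in (lm1, lm2, rim[lm3_idx], rim[lm4_idx]):
            theta = np.arctan2(
                anchor[1] * surface.length, anchor[0] * surface.width
            )
            rho_grid = np.linspace(0.0, 1.0, 257)
            z = surface.depth(rho_grid, np.full_like(rho_grid, theta))
            above = np.nonzero(z >= half_depth)[0]
            k = int(above[0]) if above.size else len(rho_grid) - 1
            if k == 0:
                rho_star = 0.0
            else:
                z0, z1 = z[k - 1], z[k]
                frac = 0.0 if z1 == z0 else (half_depth - z0) / (z1 - z0)
                rho_star = rho_grid[k - 1] + frac * (rho_grid[k] - rho_grid[k - 1])
            u = (theta / (2.0 * np.pi)) % 1.0
            coords.append(surface.point(u, rho_star))

    labels = SCHEME_LM17 if scheme == "LM17" else SCHEME_LM5
    return LandmarkConfiguration(pit_id="", labels=labels, coords=np.asarray(coords))


def apply_analyst_noise(
    config: LandmarkConfiguration,
    profile: AnalystProfile,
    rng: np.random.Generator,
) -> LandmarkConfiguration:
    """Displace each landmark by an isotropic direction times a log-normal
    magnitude whose median equals the profile's per-landmark scale."""
    profile.validate(config.labels)
    k = len(config)
    directions = rng.standard_normal((k, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    scales = np.array([profile.per_landmark_noise_scale[lab] for lab in config.labels])
    magnitudes = scales * np.exp(profile.noise_skew * rng.standard_normal(k))
    return config.replace(
        coords=config.coords + directions * magnitudes[:, None],
        analyst_id=profile.analyst_id,
    )


def generate_observer_study(cfg: ObserverStudyConfig) -> ObserverDataset:
    """Simulate a full observer study: per pit, one true configuration and
    one noise-corrupted configuration per analyst.  Deterministic in seed."""
    cfg.validate()
    labels = parse_scheme(cfg.landmark_scheme)
    analysts = list(cfg.analysts) if cfg.analysts is not None else default_analysts(labels)
    for a in analysts:
        a.validate(labels)
    rng = np.random.default_rng(cfg.seed)

    hybrid_grid_n = None
    if cfg.landmark_scheme.startswith("hybrid"):
        hybrid_grid_n = int(round(np.sqrt(len(labels) - 5)))

    configurations: list[LandmarkConfiguration] = []
    truths: dict[str, LandmarkConfiguration] = {}
    for params, prefix in ((cfg.wolf, "W"), (cfg.dog, "D")):
        for i in range(cfg.n_pits_per_carnivore):
            pit_id = f"{prefix}{i + 1:02d}"
            surface = generate_pit_surface(params, rng)
            if hybrid_grid_n is not None:
                from .semilandmarks import hybrid_true_configuration

                truth = hybrid_true_configuration(surface, grid_n=hybrid_grid_n)
            else:
                truth = true_landmarks(surface, cfg.landmark_scheme)
            truth = truth.replace(pit_id=pit_id, carnivore_label=params.carnivore_label)
            truths[pit_id] = truth
            for profile in analysts:
                configurations.append(apply_analyst_noise(truth, profile, rng))
    return ObserverDataset(configurations=configurations, true_configurations=truths)
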