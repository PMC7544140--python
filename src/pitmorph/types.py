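"""Core containers for landmark-based tooth-pit morphometry.

A *landmark configuration* is one specimen's ordered set of labelled 3D
points, in millimetres, as digitised by one analyst (or by the simulator's
ground truth).  An *observer dataset* is the specimen x analyst panel of
configurations the error analyses operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

#: Labels of the original 17-landmark tooth-pit scheme (LM1-2: maximum
#: length rim axis, LM3-4: maximum width rim axis, LM5: deepest point,
#: LM6-13: rim points between the axes, LM14-17: interior mid-depth points).
SCHEME_LM17: tuple[str, ...] = tuple(f"LM{i}" for i in range(1, 18))

#: The revised fixed-landmark scheme: the five Type II points only.
SCHEME_LM5: tuple[str, ...] = SCHEME_LM17[:5]


def hybrid_scheme_labels(grid_n: int) -> tuple[str, ...]:
    """Labels of the hybrid scheme: LM1-5 plus a grid_n x grid_n semilandmark
    patch in row-major order (``SL1`` .. ``SL{grid_n**2}``)."""
    return SCHEME_LM5 + tuple(f"SL{i}" for i in range(1, grid_n**2 + 1))


def parse_scheme(name: str) -> tuple[str, ...]:
    """Resolve a scheme name (``LM17``, ``LM5`` or ``hybridNN``) to labels.

    ``hybridNN`` must satisfy NN = 5 + n*n for an integer grid size n >= 2,
    e.g. ``hybrid30`` is the 5 fixed landmarks plus a 5x5 patch.
    """
    if name == "LM17":
        return SCHEME_LM17
    if name == "LM5":
        return SCHEME_LM5
    if name.startswith("hybrid"):
        try:
            total = int(name[len("hybrid"):])
        except ValueError:
            raise UnsupportedSchemeError(f"unknown landmark scheme {name!r}") from None
        grid_n = int(round(np.sqrt(total - 5)))
        if grid_n < 2 or 5 + grid_n**2 != total:
            raise UnsupportedSchemeError(
                f"hybrid scheme size {total} is not 5 + n*n for integer n >= 2"
            )
        return hybrid_scheme_labels(grid_n)
    raise UnsupportedSchemeError(f"unknown landmark scheme {name!r}")


class UnsupportedSchemeError(ValueError):
    """Raised for landmark scheme names the package does not know."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's ordered, labelled 3D landmark set (mm)."""

    pit_id: str
    labels: tuple[str, ...]
    coords: np.ndarray  # (k, 3) float64, mm
    analyst_id: str | None = None
    carnivore_label: str | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", tuple(self.labels))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (k, 3), got {coords.shape}")
        if len(self.labels) != coords.shape[0]:
            raise ValueError("labels and coords length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("landmark labels must be unique")
        if not np.all(np.isfinite(coords)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def landmarks(self) -> Iterator[tuple[str, np.ndarray]]:
        yield from zip(self.labels, self.coords)

    def position(self, label: str) -> np.ndarray:
        return self.coords[self.labels.index(label)]

    def subset(self, labels: Sequence[str]) -> "LandmarkConfiguration":
        """Restrict to ``labels`` (order taken from ``labels``)."""
        idx = [self.labels.index(lab) for lab in labels]
        return self.replace(labels=tuple(labels), coords=self.coords[idx])

    def replace(self, **kwargs) -> "LandmarkConfiguration":
        data = {
            "pit_id": self.pit_id,
            "labels": self.labels,
            "coords": self.coords,
            "analyst_id": self.analyst_id,
            "carnivore_label": self.carnivore_label,
        }
        data.update(kwargs)
        return LandmarkConfiguration(**data)


@dataclass
class ObserverDataset:
    """The specimen x analyst panel of configurations for one study.

    ``true_configurations`` (optional, keyed by pit id) holds the simulator's
    noise-free ground truth and is absent for datasets read from disk.
    """

    configurations: list[LandmarkConfiguration]
    true_configurations: dict[str, LandmarkConfiguration] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValueError("dataset must contain at least one configuration")
        seen: set[tuple[str, str | None]] = set()
        scheme = self.configurations[0].labels
        for cfg in self.configurations:
            key = (cfg.pit_id, cfg.analyst_id)
            if key in seen:
                raise ValueError(f"duplicate (pit, analyst) entry {key}")
            seen.add(key)
            if cfg.labels != scheme:
                raise ValueError(
                    f"configuration {key} does not share the common landmark scheme"
                )

    @property
    def scheme(self) -> tuple[str, ...]:
        return self.configurations[0].labels

    @property
    def analysts(self) -> list[str]:
        out: list[str] = []
        for cfg in self.configurations:
            if cfg.analyst_id is not None and cfg.analyst_id not in out:
                out.append(cfg.analyst_id)
        return out

    @property
    def pits(self) -> list[tuple[str, str | None]]:
        out: list[tuple[str, str | None]] = []
        seen: set[str] = set()
        for cfg in self.configurations:
            if cfg.pit_id not in seen:
                seen.add(cfg.pit_id)
                out.append((cfg.pit_id, cfg.carnivore_label))
        return out

    def subset_scheme(self, labels: Sequence[str]) -> "ObserverDataset":
        """Dataset restricted to a landmark subset (e.g. LM1-5)."""
        return ObserverDataset(
            configurations=[c.subset(labels) for c in self.configurations],
            true_configurations={
                k: v.subset(labels) for k, v in self.true_configurations.items()
            },
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """A labelled symmetric non-negative distance matrix."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if np.any(np.isnan(values)):
            raise ValueError("distance matrix contains NaN")
        if np.any(values < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric to 1e-12")
        if np.any(np.abs(np.diag(values)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.labels)
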