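"""Synthetic event generator with known component labels.

Emulates display-transformed cytometry data: mixtures of near-normal
positive populations on the unit hypercube (components are truncated to
[0, 1] by rejection, keeping them near-normal), optionally with
mass-cytometry-style negative dimensions (a point mass at zero plus an
exponential tail mapped into the bottom of scale).  Every draw is seeded
and reproducible, and the true component label of each event is returned,
so each pipeline stage and the end-to-end recursion can be validated
without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .io_transforms import EventMatrix

__all__ = ["Component", "MixtureSpec", "generate", "fixture_library",
           "make_fixture"]


@dataclass(frozen=True)
class Component:
    weight: float
    mean: tuple[float, ...]
    sd: tuple[float, ...]           # per-dimension SD (diagonal covariance)

    def cov(self) -> np.ndarray:
        return np.diag(np.square(self.sd))


@dataclass(frozen=True)
class MixtureSpec:
    """D-dimensional mixture of truncated-normal components on [0, 1]^D."""

    D: int
    components: tuple[Component, ...]
    n: int
    style: str = "gaussian"              # or "mass_like"
    seed: int = 0
    negative_dims: tuple[int, ...] = ()  # mass_like: zero-inflated dims
    zero_fraction: float = 0.3
    exp_scale: float = 0.04
    marker_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = sum(c.weight for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValidationError(f"component weights sum to {w}, not 1")
        if self.style not in ("gaussian", "mass_like"):
            raise ValidationError(f"unknown style {self.style!r}")
        for c in self.components:
            if len(c.mean) != self.D or len(c.sd) != self.D:
                raise ValidationError("component dimension mismatch")
            if not all(0.0 < m < 1.0 for m in c.mean):
                raise ValidationError(
                    f"component mean {c.mean} outside the open unit cube; "
                    "truncation infeasible")
            if not all(s > 0 for s in c.sd):
                raise ValidationError("component SDs must be positive")


def _truncated_normal(rng: np.random.Generator, mean, sd, n: int) -> np.ndarray:
    """Rejection-sample N(mean, diag(sd^2)) truncated to [0, 1]^D."""
    mean = np.asarray(mean)
    sd = np.asarray(sd)
    out = np.empty((n, mean.size))
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=(max(n - filled, 64) * 2, mean.size))
        ok = draw[np.all((draw >= 0.0) & (draw <= 1.0), axis=1)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def generate(spec: MixtureSpec) -> tuple[EventMatrix, np.ndarray]:
    """Draw the mixture; returns (events, true component labels)."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components])
    counts = rng.multinomial(spec.n, weights)
    blocks = []
    labels = []
    for k, (comp, nk) in enumerate(zip(spec.components, counts)):
        block = _truncated_normal(rng, comp.mean, comp.sd, int(nk))
        if spec.style == "mass_like":
            for d in spec.negative_dims:
                tail = rng.exponential(spec.exp_scale, size=int(nk))
                tail[tail > 1.0] = 1.0
                zero = rng.random(int(nk)) < spec.zero_fraction
                tail[zero] = 0.0
                block[:, d] = tail
        blocks.append(block)
        labels.append(np.full(int(nk), k, dtype=np.int64))
    values = np.vstack(blocks) if blocks else np.empty((0, spec.D))
    labels = np.concatenate(labels) if labels else np.empty(0, dtype=np.int64)
    perm = rng.permutation(spec.n)
    names = list(spec.marker_names) if spec.marker_names else [
        f"D{k + 1}" for k in range(spec.D)]
    events = EventMatrix(values[perm], names,
                         np.ones(spec.D, dtype=bool), np.arange(spec.n))
    return events, labels[perm]


def _iso(weight: float, mean: tuple[float, ...], sd: float) -> Component:
    return Component(weight, mean, tuple([sd] * len(mean)))


def fixture_library() -> dict[str, MixtureSpec]:
    """Canonical named fixtures used across the test suite.

    The constants are versioned: changing them is a breaking test change.
    """
    lib = {
        "one_blob": MixtureSpec(2, (_iso(1.0, (0.5, 0.5), 0.05),), n=10_000),
        "two_blobs": MixtureSpec(2, (_iso(0.5, (0.3, 0.5), 0.03),
                                     _iso(0.5, (0.7, 0.5), 0.03)), n=20_000),
        "triangle_blobs": MixtureSpec(2, (_iso(1 / 3, (0.3, 0.3), 0.03),
                                          _iso(1 / 3, (0.7, 0.3), 0.03),
                                          _iso(1 / 3, (0.5, 0.75), 0.03)),
                                      n=30_000),
        "chain_blobs": MixtureSpec(2, (_iso(1 / 3, (0.2, 0.5), 0.03),
                                       _iso(1 / 3, (0.5, 0.5), 0.03),
                                       _iso(1 / 3, (0.8, 0.5), 0.03)),
                                   n=30_000),
        "four_grid": MixtureSpec(2, (_iso(0.25, (0.3, 0.3), 0.03),
                                     _iso(0.25, (0.3, 0.7), 0.03),
                                     _iso(0.25, (0.7, 0.3), 0.03),
                                     _iso(0.25, (0.7, 0.7), 0.03)), n=40_000),
        "tiny_plus_overlap": MixtureSpec(
            2, (_iso(0.49, (0.30, 0.50), 0.055),
                _iso(0.49, (0.62, 0.50), 0.055),
                _iso(0.02, (0.85, 0.85), 0.02)), n=30_000),
        "pair13_only": MixtureSpec(
            3, (Component(0.5, (0.3, 0.5, 0.3), (0.03, 0.05, 0.03)),
                Component(0.5, (0.7, 0.5, 0.7), (0.03, 0.05, 0.03))),
            n=20_000),
    }
    # many_spikes: three well-separated groups of five tight spikes each;
    # at W = 0.01 the spikes resolve into > 12 modes, forcing kernel widening.
    spikes = []
    for cx in (0.2, 0.5, 0.8):
        for dx, dy in ((0.0, 0.0), (0.035, 0.0), (-0.035, 0.0),
                       (0.0, 0.035), (0.0, -0.035)):
            spikes.append(_iso(1 / 15, (cx + dx, 0.5 + dy), 0.008))
    lib["many_spikes"] = MixtureSpec(2, tuple(spikes), n=30_000)
    return lib


def make_fixture(name: str, n: int | None = None,
                 seed: int | None = None) -> tuple[EventMatrix, np.ndarray]:
    """Generate a named fixture, optionally overriding size and seed."""
    lib = fixture_library()
    if name not in lib:
        raise ValidationError(f"unknown fixture {name!r}; have {sorted(lib)}")
    spec = lib[name]
    if n is not None:
        spec = replace(spec, n=n)
    if seed is not None:
        spec = replace(spec, seed=seed)
    return generate(spec)
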