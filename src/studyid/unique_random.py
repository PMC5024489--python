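"""Layer intervals, pool capacity and guaranteed-unique random drawing.

The k-digit number range [10^(k-1), 10^k) is split into three equal
thirds, one per identifier layer:

    P  [1*10^(k-1), 4*10^(k-1))     personal-data IDs
    S  [4*10^(k-1), 7*10^(k-1))     study-data IDs
    T  [7*10^(k-1), 10*10^(k-1))    temporary linkage IDs

so every layer owns 3*10^(k-1) numbers and the layer of any number is
recoverable from its value.  External IDs (layer E) draw from the full
(k+1)-digit range and therefore cannot collide with any study layer.

Numbers are drawn by rejection sampling against the set of previously
issued numbers; when the request exceeds half of the remaining pool the
draw switches to sampling without replacement from the residual set,
which keeps the output uniform while avoiding the quadratic slowdown of
pure rejection near exhaustion.
"""

from __future__ import annotations

import dataclasses
import random
from typing import Optional

from .id_model import Layer, LayerInterval

__all__ = [
    "NumberPool",
    "PoolExhaustedError",
    "RandomSource",
    "capacity",
    "draw_unique",
    "external_pool",
    "layer_interval",
    "layer_of_number",
    "layer_width",
]

_K_MIN, _K_MAX = 2, 9

# Multipliers of 10^(k-1) bounding each layer's third of the k-digit range.
_LAYER_BOUNDS = {Layer.P: (1, 4), Layer.S: (4, 7), Layer.T: (7, 10)}


class PoolExhaustedError(RuntimeError):
    """A draw was requested from a pool with too few numbers left."""


def _check_k(k: int) -> None:
    if not (_K_MIN <= k <= _K_MAX):
        raise ValueError(f"random-number length k={k} outside the supported range 2..9")


def layer_width(k: int) -> int:
    """Size of one layer's third of the k-digit range, 3*10^(k-1).

    Pure arithmetic, not range-checked; :func:`capacity` is the checked
    form for supported lengths.
    """
    return 3 * 10 ** (k - 1)


def capacity(k: int) -> int:
    """Number of distinct random numbers available per layer (3*10^(k-1))."""
    _check_k(k)
    return layer_width(k)


def layer_interval(k: int, layer: Layer) -> LayerInterval:
    """Half-open number range owned by layer P, S or T at length k."""
    _check_k(k)
    layer = Layer(layer)
    if layer not in _LAYER_BOUNDS:
        raise ValueError(f"layer {layer.value} has no fixed k-digit interval")
    lo_mult, hi_mult = _LAYER_BOUNDS[layer]
    base = 10 ** (k - 1)
    return LayerInterval(layer, lo_mult * base, hi_mult * base)


def external_pool(k: int) -> LayerInterval:
    """Full (k+1)-digit range for external IDs; one digit longer than the study's k."""
    if not (_K_MIN <= k <= _K_MAX - 1):
        raise ValueError(f"external IDs need length k+1 <= 9, got k={k}")
    return LayerInterval(Layer.E, 10**k, 10 ** (k + 1))


def layer_of_number(number: int, k: int) -> Layer:
    """Recover the layer owning a k-digit number from its value alone."""
    for layer in (Layer.P, Layer.S, Layer.T):
        if number in layer_interval(k, layer):
            return layer
    raise ValueError(f"number {number} lies in no layer interval for k={k}")


@dataclasses.dataclass
class RandomSource:
    """Seedable random stream with a label separating independent uses.

    The same (seed, label) pair always replays the same draw sequence;
    distinct labels give independent streams, so e.g. number draws and
    file-row shuffles cannot leak into each other.  Without a seed the
    stream is initialized from system entropy.
    """

    seed: Optional[int] = None
    stream_label: str = "draw"
    _gen: Optional[random.Random] = dataclasses.field(
        default=None, repr=False, compare=False
    )

    def generator(self) -> random.Random:
        """The underlying generator; created lazily, then continued."""
        if self._gen is None:
            if self.seed is None:
                self._gen = random.Random()
            else:
                self._gen = random.Random(f"{self.seed}/{self.stream_label}")
        return self._gen

    def stream(self, label: str) -> "RandomSource":
        """A fresh source with the same seed and a different label."""
        return RandomSource(self.seed, label)


@dataclasses.dataclass
class NumberPool:
    """A layer interval together with the numbers already issued from it."""

    interval: LayerInterval
    used: set[int] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        bad = [n for n in self.used if n not in self.interval]
        if bad:
            raise ValueError(f"used numbers {sorted(bad)[:5]} outside interval {self.interval}")

    @property
    def layer(self) -> Layer:
        return self.interval.layer

    @property
    def remaining(self) -> int:
        return self.interval.size - len(self.used)


def draw_unique(pool: NumberPool, n: int, rng: RandomSource) -> list[int]:
    """Draw n pairwise-distinct numbers from the pool, never repeating history.

    The draw fails up front (pool untouched) when fewer than n numbers
    remain.  Returned numbers are appended to ``pool.used`` in draw
    order.
    """
    if n < 1:
        raise ValueError(f"draw count must be >= 1, got {n}")
    if n > pool.remaining:
        raise PoolExhaustedError(
            f"requested {n} numbers but only {pool.remaining} remain in "
            f"[{pool.interval.lower}; {pool.interval.upper})"
        )
    gen = rng.generator()
    lo, hi = pool.interval.lower, pool.interval.upper
    out: list[int] = []
    while len(out) < n:
        need = n - len(out)
        # Near exhaustion rejection sampling stalls; enumerate the residual
        # set once and sample it without replacement instead.
        if need > pool.remaining // 2:
            residual = [x for x in range(lo, hi) if x not in pool.used]
            picks = gen.sample(residual, need)
            pool.used.update(picks)
            out.extend(picks)
            break
        x = gen.randrange(lo, hi)
        if x in pool.used:
            continue
        pool.used.add(x)
        out.append(x)
    return out
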