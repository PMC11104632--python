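"""Seeded pseudorandom number generators for stimulus synthesis.

Two generator families are provided:

* :class:`Xorshift32` — Marsaglia's 32-bit xorshift with the canonical
  shift triple (13, 17, 5).  This is the production generator: its output
  has no lattice structure at the scales relevant to a random-dot
  stimulus, so dot sequences rendered from it are spatiotemporally
  homogeneous.
* :class:`LCG` — a configurable linear congruential generator
  ``x' = (a*x + c) mod m``.  LCGs suffer from the well-known lattice
  ("hyperplane") defect; the RANDU-style preset (``a=65539, c=0,
  m=2**31``) is shipped deliberately so the striping artifact it can
  produce in averaged noise sequences can be demonstrated and tested.

Both expose the same small interface: ``next_u32()`` for a single raw
draw, ``raw_block(n)`` for a vectorized batch, and
``uniform_index(k)`` / ``index_block(k, n)`` for unbiased integers in
``[0, k)`` via rejection sampling (raw values at or above
``floor(max/k)*k`` are discarded, which removes modulo bias).

Reproducibility contract: a given ``(algorithm, seed)`` pair always
yields the same stream, and block draws consume the stream exactly as
repeated scalar draws would.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import ConfigError, InvalidStateError

_MASK32 = 0xFFFFFFFF

#: Documented replacement state used when a xorshift generator is seeded
#: with 0 (the all-zero word is a fixed point of the xorshift map).
XORSHIFT_ZERO_SEED_REMAP = 123456789


class Xorshift32:
    """Marsaglia xorshift generator, 32-bit state, shifts (13, 17, 5).

    Parameters
    ----------
    seed:
        Initial state, taken modulo 2**32.  Seed 0 is remapped to
        :data:`XORSHIFT_ZERO_SEED_REMAP` because 0 is a fixed point.
    """

    shifts: Tuple[int, int, int] = (13, 17, 5)
    #: Raw draws lie in [0, max_value).
    max_value: int = 1 << 32

    def __init__(self, seed: int) -> None:
        state = int(seed) & _MASK32
        if state == 0:
            state = XORSHIFT_ZERO_SEED_REMAP
        self._state = state

    @property
    def state(self) -> int:
        return self._state

    @state.setter
    def state(self, value: int) -> None:
        value = int(value)
        if not 0 < value < (1 << 32):
            raise InvalidStateError(
                f"xorshift32 state must be a nonzero 32-bit word, got {value}"
            )
        self._state = value

    def next_u32(self) -> int:
        x = self._state
        if x == 0:  # unreachable through the public API, but guard anyway
            raise InvalidStateError("xorshift32 state is 0")
        x ^= (x << 13) & _MASK32
        x ^= x >> 17
        x ^= (x << 5) & _MASK32
        self._state = x
        return x

    def raw_block(self, n: int) -> np.ndarray:
        """Draw ``n`` raw values as a uint32 array."""
        out = np.empty(int(n), dtype=np.uint32)
        x = self._state
        for i in range(int(n)):
            x ^= (x << 13) & _MASK32
            x ^= x >> 17
            x ^= (x << 5) & _MASK32
            out[i] = x
        self._state = x
        return out

    # rejection sampling shared with LCG
    def uniform_index(self, k: int) -> int:
        return _uniform_index(self, k)

    def index_block(self, k: int, n: int) -> np.ndarray:
        return _index_block(self, k, n)

    def clone(self) -> "Xorshift32":
        dup = Xorshift32(1)
        dup._state = self._state
        return dup


class LCG:
    """Linear congruential generator ``x' = (a*x + c) mod m``.

    The emitted value is the updated state, so raw draws lie in
    ``[0, m)``.  With ``a=1, c=0`` any seed is a fixed point — this
    degenerate configuration is permitted because it is occasionally
    useful in tests.
    """

    def __init__(self, seed: int, a: int, c: int, m: int) -> None:
        if m <= 1:
            raise ConfigError(f"LCG modulus must exceed 1, got {m}")
        if not (0 < a < m) or not (0 <= c < m):
            raise ConfigError(f"LCG parameters out of range: a={a}, c={c}, m={m}")
        self.a = int(a)
        self.c = int(c)
        self.m = int(m)
        self._state = int(seed) % self.m
        if self._state == 0 and c == 0:
            # the zero state is absorbing for multiplicative LCGs
            self._state = 1

    @classmethod
    def randu(cls, seed: int) -> "LCG":
        """The classic RANDU parameters (a=65539, c=0, m=2**31).

        RANDU is the canonical example of a catastrophically bad LCG:
        consecutive triples satisfy ``x[n+2] = 6*x[n+1] - 9*x[n] (mod
        2**31)`` and fall on 15 planes, and powers of the multiplier are
        2-adically close to 1, which produces strong correlations at
        fixed lags.  Used only for the inhomogeneity demonstration.
        """
        g = cls(seed, a=65539, c=0, m=1 << 31)
        if g._state % 2 == 0:
            g._state += 1  # RANDU is usually run on odd seeds
        return g

    @property
    def max_value(self) -> int:
        return self.m

    @property
    def state(self) -> int:
        return self._state

    def next_u32(self) -> int:
        self._state = (self.a * self._state + self.c) % self.m
        return self._state

    def raw_block(self, n: int) -> np.ndarray:
        out = np.empty(int(n), dtype=np.uint32)
        x, a, c, m = self._state, self.a, self.c, self.m
        for i in range(int(n)):
            x = (a * x + c) % m
            out[i] = x
        self._state = x
        return out

    def uniform_index(self, k: int) -> int:
        return _uniform_index(self, k)

    def index_block(self, k: int, n: int) -> np.ndarray:
        return _index_block(self, k, n)

    def clone(self) -> "LCG":
        dup = LCG(self._state, self.a, self.c, self.m)
        dup._state = self._state
        return dup


def _uniform_index(gen, k: int) -> int:
    """Unbiased integer in [0, k) by rejection on the raw stream."""
    k = int(k)
    if k <= 0:
        raise ConfigError(f"uniform_index requires k >= 1, got {k}")
    if k == 1:
        return 0
    limit = (gen.max_value // k) * k
    while True:
        raw = gen.next_u32()
        if raw < limit:
            return raw % k


def _index_block(gen, k: int, n: int) -> np.ndarray:
    """Vectorized rejection sampling; consumes the stream in the same
    order as ``n`` successive scalar ``uniform_index`` calls."""
    k = int(k)
    n = int(n)
    if k <= 0:
        raise ConfigError(f"index_block requires k >= 1, got {k}")
    if k == 1:
        return np.zeros(n, dtype=np.int64)
    limit = (gen.max_value // k) * k
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        raw = gen.raw_block(n - filled)
        accepted = raw[raw < np.uint64(limit)].astype(np.int64) % k
        out[filled : filled + accepted.size] = accepted
        filled += accepted.size
    return out


@dataclass(frozen=True)
class RNGSpec:
    """Serializable description of a generator: algorithm, seed, and —
    for LCGs only — the (a, c, m) triple."""

    algorithm: str = "xorshift32"
    seed: int = 1
    lcg_params: Optional[Tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        if self.algorithm not in ("xorshift32", "lcg"):
            raise ConfigError(f"unknown RNG algorithm: {self.algorithm!r}")

    def make(self):
        return make_generator(self.algorithm, self.seed, self.lcg_params)


#: Default poor-LCG preset used when an ``RNGSpec`` asks for "lcg"
#: without explicit parameters.
RANDU_PARAMS: Tuple[int, int, int] = (65539, 0, 1 << 31)


def make_generator(algorithm: str, seed: int,
                   lcg_params: Optional[Tuple[int, int, int]] = None):
    """Instantiate a generator by name.

    ``algorithm`` is ``"xorshift32"`` or ``"lcg"``; for ``"lcg"`` the
    optional ``lcg_params`` triple ``(a, c, m)`` defaults to the
    RANDU-style preset.
    """
    if algorithm == "xorshift32":
        return Xorshift32(seed)
    if algorithm == "lcg":
        a, c, m = lcg_params if lcg_params is not None else RANDU_PARAMS
        return LCG(seed, a=a, c=c, m=m)
    raise ConfigError(f"unknown RNG algorithm: {algorithm!r}")
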