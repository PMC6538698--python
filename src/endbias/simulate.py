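"""Seeded simulator of equimolar pools sequenced with terminal-position bias.

Species m is sampled with probability

    p_m ∝ 10 ** (sum_i effect(i, base(m, i)) + length_slope * len_m)

so biases compose multiplicatively (log-additively), matching the additive
log-scale regression target of the corrector. Counts are multinomial at a
fixed depth; technical replicates are independent draws from the same p.
The ground truth Δlog10CPM of species m is log10(p_m · n), its deviation
from uniform representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biascorrect import base_at
from .overhangdesign import OVERHANG_CAPTURES, OverhangRatio
from .seqio import CountTable, ReferencePool


@dataclass
class BiasSpec:
    """Ground-truth positional effects driving the simulator.

    ``effects`` maps (signed position, base) to a log10 effect; unlisted
    pairs are 0. ``length_slope`` is log10 CPM per nt (0 by default; 0.09
    reproduces the weak length dependence seen in real pools).
    """

    effects: dict[tuple[int, str], float] = field(default_factory=dict)
    length_slope: float = 0.0
    seed: int = 0
    depth: int = 1_000_000

    def __post_init__(self) -> None:
        for (pos, base), eff in self.effects.items():
            if pos == 0 or base not in "ACGT" or not math.isfinite(eff):
                raise ValueError(f"invalid effect entry {(pos, base, eff)}")
        if self.depth < 1:
            raise ValueError("depth must be positive")

    @classmethod
    def tgirt_like(cls, seed: int = 0, depth: int = 1_000_000) -> "BiasSpec":
        """Terminal biases emulating a template-switching/ssDNA-ligation
        library: 5' favors +1U(T), +2G, +3G and disfavors A; the 3'
        terminal base dominates, favoring G and disfavoring U(T)."""
        effects = {
            (1, "T"): 0.25, (1, "A"): -0.25,
            (2, "G"): 0.25, (2, "A"): -0.25,
            (3, "G"): 0.20, (3, "A"): -0.20,
            (-1, "G"): 0.45, (-1, "T"): -0.45,
            (-2, "G"): 0.10, (-2, "A"): -0.10,
            (-3, "C"): 0.10, (-3, "T"): -0.10,
        }
        return cls(effects=effects, seed=seed, depth=depth)

    def with_overhang_ratio(self, ratio: OverhangRatio) -> "BiasSpec":
        """Add a skewed 3'-overhang mix as a multiplicative acceptance
        factor at position -1: a species whose 3' base is captured by
        overhang d gains log10(share_d / 0.25) relative to an equimolar
        mix."""
        effects = dict(self.effects)
        for d, b in OVERHANG_CAPTURES.items():
            effects[(-1, b)] = (effects.get((-1, b), 0.0)
                                + math.log10(ratio.shares[d] / 0.25))
        return BiasSpec(effects=effects, length_slope=self.length_slope,
                        seed=self.seed, depth=self.depth)


@dataclass
class SimulatedTruth:
    """True sampling probabilities and Δlog10CPM vs uniform."""

    probabilities: pd.Series
    delta_log10: pd.Series


def simulate_pool(
    n: int = 962,
    length_range: tuple[int, int] = (19, 25),
    seed: int = 0,
) -> ReferencePool:
    """n unique random sequences, i.i.d. uniform bases, uniform lengths."""
    lo, hi = length_range
    if n < 1:
        raise ValueError("n must be at least 1")
    if lo < 6 or hi < lo:
        raise ValueError("lengths must be >= 6 with lo <= hi")
    capacity = sum(4 ** L for L in range(lo, hi + 1))
    if n > capacity:
        raise ValueError(f"cannot draw {n} distinct sequences of length "
                         f"{lo}-{hi} (only {capacity} exist)")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    entries: list[tuple[str, str]] = []
    while len(entries) < n:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(bases, size=length))
        if seq in seen:
            continue
        seen.add(seq)
        entries.append((f"syn-mir-{len(entries) + 1:04d}", seq))
    return ReferencePool(entries=entries, name=f"simulated-pool-n{n}")


def true_probabilities(pool: ReferencePool, spec: BiasSpec) -> SimulatedTruth:
    """Closed-form sampling probabilities implied by a bias spec."""
    logp = pd.Series(0.0, index=pd.Index(pool.ids))
    for ident, seq in pool:
        total = spec.length_slope * len(seq)
        for (pos, base), eff in spec.effects.items():
            if base_at(seq, pos) == base:
                total += eff
        logp[ident] = total
    p = 10.0 ** logp
    p /= p.sum()
    return SimulatedTruth(probabilities=p,
                          delta_log10=np.log10(p * len(pool)))


def simulate_counts(
    pool: ReferencePool,
    spec: BiasSpec,
    replicates: int = 1,
) -> tuple[CountTable, SimulatedTruth]:
    """Multinomial counts at ``spec.depth`` per replicate, plus the truth."""
    truth = true_probabilities(pool, spec)
    rng = np.random.default_rng(spec.seed)
    draws = {
        f"sim{r + 1}": rng.multinomial(spec.depth,
                                       truth.probabilities.to_numpy())
        for r in range(replicates)
    }
    table = CountTable(pd.DataFrame(draws, index=truth.probabilities.index,
                                    dtype=float))
    return table, truth
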