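"""Design-side utilities for template-switching library preparation.

Template-switching initiates on a starter duplex whose single 3'-DNA
overhang base-pairs with the RNA's 3'-terminal base (dA captures U/T-ending
RNAs, dC captures G, dG captures C, dT captures A). Skewing the A:C:G:T mix
of overhangs therefore compensates for 3'-end capture bias: a base class
recovered below its expected share gets proportionally more of its
complementary overhang. The empirically titrated compensating mix for the
equimolar reference pool is A:C:G:T = 6.6:0.4:1:1 (preset ``NTTR``).

The module also scores an adapter's propensity to form adapter dimers from
the single-stranded ligase's acceptor preference at position -3 (A or C
favored, T/U disfavored).
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import canonicalize_sequence

#: 3'-overhang DNA base -> RNA 3'-terminal base it captures
OVERHANG_CAPTURES = {"A": "T", "C": "G", "G": "C", "T": "A"}

RATIO_CLIP = 10.0


@dataclass(frozen=True)
class OverhangRatio:
    """A:C:G:T weights of the 3'-overhang nucleotides in the primer mix."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.weights) != set("ACGT"):
            raise ValueError("weights must cover exactly A, C, G, T")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all overhang weights must be positive")

    @property
    def shares(self) -> dict[str, float]:
        total = sum(self.weights.values())
        return {b: w / total for b, w in self.weights.items()}

    @classmethod
    def equimolar(cls) -> "OverhangRatio":
        return cls(weights={b: 1.0 for b in "ACGT"})


#: named primer-mix presets; NTC/NTT/MTT use an equimolar overhang mix
#: (they differ in adapter sequence or a diaminopurine in place of dA),
#: NTTR is the titrated compensating mix.
PRESETS: dict[str, OverhangRatio] = {
    "NTC": OverhangRatio.equimolar(),
    "NTT": OverhangRatio.equimolar(),
    "MTT": OverhangRatio.equimolar(),
    "NTTR": OverhangRatio(weights={"A": 6.6, "C": 0.4, "G": 1.0, "T": 1.0}),
}


def design_overhang_ratio(
    recovered: dict[str, float],
    expected: dict[str, float],
    current: OverhangRatio,
) -> OverhangRatio:
    """First-order compensating overhang mix.

    Each overhang weight is multiplied by ``expected(b)/recovered(b)`` for
    the RNA 3' base b it captures, then renormalized to the scale of the
    current mix. At the fixpoint (recovered == expected) the mix is
    returned unchanged. The ratio is clipped at 10 when a base class is
    unrecovered. This proportional rule is advisory: the published
    compensating mix was found by empirical titration.
    """
    for base in "ACGT":
        if recovered.get(base, 0.0) > 0 and expected.get(base, 0.0) == 0:
            raise ValueError(
                f"expected share of 3'-{base} is zero but it was recovered; "
                "degenerate target distribution")
    new = {}
    for d, b in OVERHANG_CAPTURES.items():
        rec = recovered.get(b, 0.0)
        exp = expected.get(b, 0.0)
        ratio = RATIO_CLIP if rec == 0 else min(exp / rec, RATIO_CLIP)
        new[d] = current.weights[d] * ratio
    scale = sum(current.weights.values()) / sum(new.values())
    return OverhangRatio(weights={d: w * scale for d, w in new.items()})


def adapter_ligation_screen(adapter_seq: str) -> tuple[str, str]:
    """Score an adapter's adapter-dimer propensity from its -3 base.

    The single-stranded ligase prefers A or C and disfavors T/U at position
    -3 of the acceptor, so an adapter carrying A/C there readily acts as a
    ligation acceptor in dimer formation (high), G is intermediate, and T
    suppresses dimers (low). Returns ``(minus3_base, propensity)``.
    """
    seq = canonicalize_sequence(adapter_seq, "<adapter>")
    if len(seq) < 3:
        raise ValueError("adapter must be at least 3 nt to have a -3 base")
    minus3 = seq[-3]
    propensity = {"A": "high", "C": "high", "G": "medium", "T": "low"}[minus3]
    return minus3, propensity
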