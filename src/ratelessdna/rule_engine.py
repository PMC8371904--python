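"""DNA stability rules: per-sequence error scoring and erasure decisions.

Synthesis, PCR and sequencing are unreliable on certain sequence motifs:
long homopolymer runs, unbalanced GC content (overall and per window),
micro-satellites (di-/trinucleotide tandem repeats), and per-base mutation
susceptibility.  Each enabled rule contributes an error value in [0, 1];
contributions add up (and may exceed 1 when several rules fire) and the
sum, times a global ``scale`` calibration factor, is the sequence's error
score.  The score times the number of storage generations, clamped to 1,
is the probability that the erasure channel drops the sequence.

The rule families and the GC error curve follow the published calibration
sources; exact thresholds for homopolymer and repeat curves are
configuration with conservative defaults, deliberately overestimating so
the score is a close upper bound that can be scaled down as needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .dna_layer import DnaSequence
from .distributions import DeterministicRng
from .errors import ParameterError

__all__ = [
    "RuleConfig",
    "RuleReport",
    "gc_content",
    "gc_error",
    "homopolymer_error",
    "microsatellite_error",
    "windowed_gc_error",
    "longest_homopolymer",
    "longest_tandem_repeat",
    "total_error",
    "drop_decision",
    "preset",
    "default_rules",
    "erlich_zielinski_rules",
]

_BASES = frozenset("ACGT")

# step curves: ((threshold, value), ...) sorted ascending; value at x is the
# entry with the largest threshold <= x, or 0 below the first threshold
DEFAULT_HOMOPOLYMER_CURVE = ((4, 0.3), (5, 0.7), (6, 1.0))
DEFAULT_DINUCLEOTIDE_CURVE = ((4, 0.5), (5, 0.8), (6, 1.0))
DEFAULT_TRINUCLEOTIDE_CURVE = ((3, 0.5), (4, 0.8), (5, 1.0))


def step_value(curve, x: int) -> float:
    out = 0.0
    for threshold, value in curve:
        if x >= threshold:
            out = value
        else:
            break
    return out


def _bases_of(seq) -> str:
    return seq.bases if isinstance(seq, DnaSequence) else seq


def gc_content(seq) -> float:
    """GC percentage: (|G|+|C|) / (|G|+|C|+|A|+|T|) * 100."""
    bases = _bases_of(seq)
    if not bases:
        raise ParameterError("gc_content of an empty sequence is undefined")
    gc = bases.count("G") + bases.count("C")
    return gc / len(bases) * 100.0


# GC error quartic: f(x) = (-x^4/7200 + x^3/36 - 121 x^2/72 + 175 x/6
#                           + 100) / 100, clamped to [0, 1].
# Exactly 0 on [40, 60] and exactly 1 on [0, 30] and [70, 100]; near-linear
# ramps in between.  Evaluated in exact rational arithmetic so the plateau
# boundaries are hit exactly rather than to rounding error.
def gc_error(gc_percent: float) -> float:
    if not 0 <= gc_percent <= 100:
        raise ParameterError("GC percentage must lie in [0, 100]")
    x = Fraction(gc_percent)
    f = (-x ** 4 / 7200 + x ** 3 / 36 - Fraction(121) * x ** 2 / 72
         + Fraction(175) * x / 6 + 100) / 100
    return float(max(min(f, Fraction(1)), Fraction(0)))


def _gc_error_vec(gc_percent: np.ndarray) -> np.ndarray:
    x = np.asarray(gc_percent, dtype=float)
    f = (-x ** 4 / 7200 + x ** 3 / 36 - 121 * x ** 2 / 72 + 175 * x / 6
         + 100) / 100
    return np.clip(f, 0.0, 1.0)


def longest_homopolymer(seq) -> int:
    bases = _bases_of(seq)
    if not bases:
        return 0
    best = run = 1
    for prev, cur in zip(bases, bases[1:]):
        run = run + 1 if cur == prev else 1
        if run > best:
            best = run
    return best


def homopolymer_error(seq, curve=DEFAULT_HOMOPOLYMER_CURVE) -> float:
    """Error of the longest single-base run, through a monotone step curve."""
    return step_value(curve, longest_homopolymer(seq))


def longest_tandem_repeat(seq, unit_length: int) -> int:
    """Largest m such that some substring is m back-to-back copies of a
    ``unit_length``-mer.  Linear scan over the lag-u self-match profile: a
    stretch of r consecutive matches means a periodic substring of length
    r + u, i.e. (r + u) // u unit copies."""
    bases = _bases_of(seq)
    u = unit_length
    if len(bases) < u:
        return 0
    best = 1
    run = 0
    for i in range(u, len(bases)):
        if bases[i] == bases[i - u]:
            run += 1
            copies = (run + u) // u
            if copies > best:
                best = copies
        else:
            run = 0
    return best


def microsatellite_error(seq, unit_length: int, curve=None) -> float:
    """Micro-satellite (short tandem repeat) error for di- or trinucleotide
    units, mapping the longest repeat count through a step curve."""
    if unit_length not in (2, 3):
        raise ParameterError("unit_length must be 2 or 3")
    if curve is None:
        curve = (DEFAULT_DINUCLEOTIDE_CURVE if unit_length == 2
                 else DEFAULT_TRINUCLEOTIDE_CURVE)
    return step_value(curve, longest_tandem_repeat(seq, unit_length))


def windowed_gc_error(seq, window: int) -> float:
    """Worst (maximum) GC error over all sliding windows; equals the plain
    GC error when the window spans the whole sequence."""
    bases = _bases_of(seq)
    if window < 1 or window > len(bases):
        raise ParameterError("window must satisfy 1 <= window <= length")
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int32)
    csum = np.concatenate(([0], np.cumsum(gc)))
    counts = csum[window:] - csum[:-window]
    return float(_gc_error_vec(counts / window * 100.0).max())


@dataclass(frozen=True)
class RuleConfig:
    """Enabled rules and their parameters.

    ``rules`` names the active checks; ``scale`` is the global calibration
    multiplier applied to the accumulated score (the default rules are
    deliberate overestimates)."""

    rules: tuple[str, ...]
    homopolymer_curve: tuple = DEFAULT_HOMOPOLYMER_CURVE
    dinucleotide_curve: tuple = DEFAULT_DINUCLEOTIDE_CURVE
    trinucleotide_curve: tuple = DEFAULT_TRINUCLEOTIDE_CURVE
    gc_window: int = 50
    illegal_motifs: tuple[str, ...] = ()
    length_limits: tuple[int | None, int | None] = (None, None)
    base_weights: dict = field(default_factory=dict)
    check_reverse_complement: bool = False
    scale: float = 1.0

    @classmethod
    def from_dict(cls, data: dict) -> "RuleConfig":
        """Build from a parsed config mapping (YAML/JSON dialect).

        Unknown keys are rejected; curves may be given as
        ``{threshold: value}`` mappings."""
        data = dict(data)
        for key in ("homopolymer_curve", "dinucleotide_curve",
                    "trinucleotide_curve"):
            if key in data and isinstance(data[key], dict):
                data[key] = tuple(sorted(
                    (int(t), float(v)) for t, v in data[key].items()))
        if "rules" in data:
            data["rules"] = tuple(data["rules"])
        if "illegal_motifs" in data:
            data["illegal_motifs"] = tuple(data["illegal_motifs"])
        if "length_limits" in data:
            data["length_limits"] = tuple(data["length_limits"])
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown rule config keys: {sorted(unknown)}")
        return cls(**data)


KNOWN_RULES = ("homopolymer", "gc", "windowed_gc", "dinucleotide",
               "trinucleotide", "illegal_symbols", "illegal_motifs",
               "length", "base_weights")

# per-base mutation susceptibility: a uniform small weight per occurrence;
# site-specific published weights are configuration, not shipped constants
DEFAULT_BASE_WEIGHTS = {"A": 0.0005, "C": 0.0005, "G": 0.0005, "T": 0.0005}


def default_rules() -> RuleConfig:
    """Full default rule set."""
    return RuleConfig(
        rules=("homopolymer", "gc", "windowed_gc", "dinucleotide",
               "trinucleotide", "illegal_symbols", "base_weights"),
        base_weights=dict(DEFAULT_BASE_WEIGHTS),
    )


def erlich_zielinski_rules() -> RuleConfig:
    """Reference rule set restricted to homopolymers and GC content."""
    return RuleConfig(rules=("homopolymer", "gc", "illegal_symbols"))


_PRESETS = {"default": default_rules, "erlich_zielinski": erlich_zielinski_rules}


def preset(name: str) -> RuleConfig:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ParameterError(
            f"unknown rule preset {name!r}; choose from {sorted(_PRESETS)}")


@dataclass(frozen=True)
class RuleReport:
    """Per-rule error contributions and the accumulated, scaled total.

    The total may exceed 1.0 — a score above 1 means several rules were
    violated at saturation."""

    per_rule: dict
    total: float


def _contributions(bases: str, config: RuleConfig) -> dict:
    per_rule: dict[str, float] = {}
    legal = set(bases) <= _BASES
    for rule in config.rules:
        if rule == "homopolymer":
            per_rule[rule] = homopolymer_error(bases, config.homopolymer_curve)
        elif rule == "gc":
            per_rule[rule] = gc_error(gc_content(bases)) if bases else 1.0
        elif rule == "windowed_gc":
            window = min(config.gc_window, len(bases))
            per_rule[rule] = windowed_gc_error(bases, window) if bases else 1.0
        elif rule == "dinucleotide":
            per_rule[rule] = microsatellite_error(
                bases, 2, config.dinucleotide_curve)
        elif rule == "trinucleotide":
            per_rule[rule] = microsatellite_error(
                bases, 3, config.trinucleotide_curve)
        elif rule == "illegal_symbols":
            per_rule[rule] = 0.0 if legal else 1.0
        elif rule == "illegal_motifs":
            per_rule[rule] = 1.0 if any(
                m in bases for m in config.illegal_motifs) else 0.0
        elif rule == "length":
            lo, hi = config.length_limits
            bad = (lo is not None and len(bases) < lo) or \
                  (hi is not None and len(bases) > hi)
            per_rule[rule] = 1.0 if bad else 0.0
        elif rule == "base_weights":
            weight = sum(config.base_weights.get(b, 0.0) for b in bases)
            per_rule[rule] = min(weight, 1.0)
        else:
            raise ParameterError(f"unknown rule {rule!r}")
    return per_rule


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def total_error(seq, config: RuleConfig) -> RuleReport:
    """Apply every enabled rule independently and accumulate.

    Contributions are summed (not multiplied) and scaled by
    ``config.scale``.  With ``check_reverse_complement`` the per-rule
    contribution is the worse of the two strands, making the score
    strand-symmetric.  A non-ACGT symbol makes the sequence unusable:
    the illegal-symbol contribution is 1.
    """
    bases = _bases_of(seq)
    per_rule = _contributions(bases, config)
    if config.check_reverse_complement and set(bases) <= _BASES:
        rc = bases.translate(_COMPLEMENT)[::-1]
        for rule, value in _contributions(rc, config).items():
            per_rule[rule] = max(per_rule[rule], value)
    total = sum(per_rule.values()) * config.scale
    return RuleReport(per_rule=per_rule, total=total)


def drop_decision(total_error_score: float, generations: int,
                  rng: DeterministicRng) -> bool:
    """Erasure decision: drop with probability min(score * generations, 1).

    Longer storage (more amplification/copy generations) multiplies the
    mutation probability; the Bernoulli draw comes from the deterministic
    generator so channel simulations are reproducible.
    """
    if generations < 1:
        raise ParameterError("generations must be >= 1")
    p = min(total_error_score * generations, 1.0)
    return rng.random() < p
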