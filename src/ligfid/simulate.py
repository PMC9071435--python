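"""Parametric generative model of competitive cohesive-end ligation.

The multiplexed assay presents every four-base overhang simultaneously, so
product formation is a competition among all 256 x 256 possible pairings.
The generator models one ligation event as a single multinomial draw over
unordered overhang pairs, with the propensity of an ordered pair (a, b)

    propensity(a, b) = w_a * w_b * exp(alpha * gc_pairs(a, b))
                       * prod over mismatches of tolerance(type, class)

where ``w_o`` is a per-overhang ligation weight, ``alpha`` scales an
annealing-strength boost per correctly paired G:C position, and the
mismatch tolerance table is keyed by unordered base-pair type (G:T and T:G
are one type) and junction position class (edge = N1/N4, middle = N2/N3).
Watson-Crick positions contribute factor 1; a tolerance of 0 forbids the
mismatch.  The propensity is symmetric, so the ordered-pair distribution is
too, and every downstream statistic has a closed-form expectation.

An optional coupling ``mismatch_anneal_coeff`` (beta, default 0) multiplies
each mismatch factor by exp(beta * gc_pairs): strongly annealed GC-rich
duplexes hold a mismatched end in place long enough to be sealed, which is
what makes observed fidelity fall with GC content.  At beta = 0 the
propensity is exactly the product form above.

``emit_reads`` turns sampled events into product strand sequences with the
degenerate-substrate layout: constant anchor, four-base overhang, constant
region carrying an independently randomised control hexamer (a monitor for
synthesis bias).  The anchors are fixed package constants; the emulation is
structural, not a reproduction of the published substrate sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import yaml

from . import overhangs as oh
from .overhangs import (
    CODES,
    COMP_CODE,
    GC_PAIR_COUNTS,
    OVERHANG_LENGTH,
    OVERHANGS,
    canonical_pair_label,
    clean_dna,
    clean_overhang,
    mismatches,
    position_class,
)

POSITION_CLASSES = ("edge", "middle")


@dataclass
class LigaseModel:
    """Generative parameters of one ligase under one buffer condition.

    Parameters
    ----------
    weights
        Per-overhang ligation propensity ``w_o`` (positive); overhangs not
        listed default to 1.0.
    anneal_coeff
        ``alpha``, the log-scale boost per correctly annealed G:C base pair.
        0 disables GC-dependent annealing bias.
    mismatch_tolerance
        Map ``(pair_type, position_class) -> tolerance in [0, 1]`` where
        ``pair_type`` is a canonical unordered label such as ``"G:T"`` and
        ``position_class`` is ``"edge"`` or ``"middle"``.  Unlisted mismatch
        types have tolerance 0 (forbidden), so the default model is
        Watson-Crick-only.
    mismatch_anneal_coeff
        ``beta``, an optional annealing-mismatch coupling: each mismatch
        factor is additionally scaled by exp(beta * gc_pairs).  0 (the
        default) leaves tolerances annealing-independent.
    """

    name: str = "uniform"
    weights: Mapping[str, float] = field(default_factory=dict)
    anneal_coeff: float = 0.0
    mismatch_tolerance: Mapping[tuple[str, str], float] = field(default_factory=dict)
    mismatch_anneal_coeff: float = 0.0

    def __post_init__(self):
        self.weights = {clean_overhang(o): float(w) for o, w in self.weights.items()}
        for o, w in self.weights.items():
            if not w > 0:
                raise ValueError(f"weight for {o} must be positive, got {w}")
        tol = {}
        for (label, cls), t in self.mismatch_tolerance.items():
            a, _, b = label.partition(":")
            key = (canonical_pair_label(a, b), cls)
            if cls not in POSITION_CLASSES:
                raise ValueError(f"unknown position class {cls!r}")
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"tolerance for {key} must be in [0, 1], got {t}")
            tol[key] = float(t)
        self.mismatch_tolerance = tol

    def weight(self, o: str) -> float:
        return self.weights.get(clean_overhang(o), 1.0)

    def tolerance(self, pair_type: str, cls: str) -> float:
        a, _, b = pair_type.partition(":")
        return self.mismatch_tolerance.get((canonical_pair_label(a, b), cls), 0.0)

    def weight_vector(self) -> np.ndarray:
        w = np.ones(256)
        for o, v in self.weights.items():
            w[oh.OVERHANG_INDEX[o]] = v
        return w


def pair_propensity(model: LigaseModel, top: str, bottom: str) -> float:
    """Unnormalised ligation propensity of one ordered overhang pair.

    Scalar reference implementation over :func:`ligfid.overhangs.mismatches`;
    the vectorised :func:`propensity_matrix` must agree with it cellwise.
    """
    top = clean_overhang(top)
    bottom = clean_overhang(bottom)
    i = oh.OVERHANG_INDEX[top]
    j = oh.OVERHANG_INDEX[bottom]
    value = model.weight(top) * model.weight(bottom)
    value *= float(np.exp(model.anneal_coeff * GC_PAIR_COUNTS[i, j]))
    for rec in mismatches(top, bottom):
        value *= model.tolerance(rec.pair_type, rec.position_class)
        value *= float(np.exp(model.mismatch_anneal_coeff * GC_PAIR_COUNTS[i, j]))
    return value


def propensity_matrix(model: LigaseModel) -> np.ndarray:
    """Propensities for all 256 x 256 ordered pairs (symmetric)."""
    w = model.weight_vector()
    prop = w[:, None] * w[None, :] * np.exp(model.anneal_coeff * GC_PAIR_COUNTS)
    for pos in range(1, OVERHANG_LENGTH + 1):
        cls = position_class(pos)
        grid = np.ones((4, 4))
        for ti in range(4):
            for bi in range(4):
                if COMP_CODE[ti] != bi:
                    label = canonical_pair_label(oh.ALPHABET[ti], oh.ALPHABET[bi])
                    grid[ti, bi] = model.tolerance(label, cls)
        top_code = CODES[:, pos - 1]
        opp_code = CODES[:, OVERHANG_LENGTH - pos]
        prop = prop * grid[top_code][:, opp_code]
    if model.mismatch_anneal_coeff != 0.0:
        prop = prop * np.exp(
            model.mismatch_anneal_coeff * GC_PAIR_COUNTS * oh.N_MISMATCHES
        )
    return prop


class ExpectedProfile:
    """Closed-form ordered-pair distribution implied by a :class:`LigaseModel`.

    ``probs`` is the normalised symmetric 256 x 256 matrix; convenience
    methods expose the exact expectations that sampled statistics converge
    to, for oracle tests.
    """

    def __init__(self, model: LigaseModel):
        prop = propensity_matrix(model)
        total = prop.sum()
        if total <= 0:
            raise ValueError("model assigns zero propensity to every pair")
        self.model = model
        self.probs = prop / total

    def overall_fidelity(self) -> float:
        """Expected fraction of Watson-Crick ligation events."""
        return float(self.probs[oh.WC_MASK].sum())

    def normalized_frequency(self) -> np.ndarray:
        """Expected per-overhang normalised frequency (mean 1 over 256)."""
        return self.probs.sum(axis=1) * 256

    def per_overhang_fidelity(self) -> np.ndarray:
        """Expected fidelity per overhang; NaN where an overhang never ligates."""
        row = self.probs.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fid = self.probs[np.arange(256), oh.RC_INDEX] / row
        fid[row == 0] = np.nan
        return fid


def expected_profile(model: LigaseModel) -> ExpectedProfile:
    """Closed-form expectation oracle for all downstream statistics."""
    return ExpectedProfile(model)


def sample_events(model: LigaseModel, n_events: int, seed: int):
    """Draw ligation events and return the dual-orientation count matrix.

    Events are unordered pair draws from the expected profile; each event is
    stored canonically by incrementing both ordered orientations (a
    palindromic self-pair adds 2 to its diagonal cell), so the total ordered
    count is ``2 * n_events``.  Reproducible for a fixed seed.
    """
    from .extract import PairCountMatrix

    if n_events <= 0:
        raise ValueError(f"n_events must be positive, got {n_events}")
    profile = expected_profile(model)
    iu, ju = np.triu_indices(256)
    p = profile.probs[iu, ju] * np.where(iu == ju, 1.0, 2.0)
    rng = np.random.default_rng(seed)
    draw = rng.multinomial(n_events, p / p.sum())
    counts = np.zeros((256, 256), dtype=np.int64)
    counts[iu, ju] += draw
    counts[ju, iu] += draw  # diagonal cells receive 2 * draw in total
    return PairCountMatrix(
        counts=counts,
        metadata={
            "sample": f"sim-{model.name}-seed{seed}",
            "ligase": model.name,
            "condition": "simulated",
            "replicates": [f"seed{seed}"],
        },
    )


DEFAULT_LEFT_CONST = "TACGGACTTGCACCTGTAGC"
DEFAULT_RIGHT_CONST = "GATCCAGTTGGCTGCTACCG"


@dataclass
class SubstrateSpec:
    """Structural layout of a ligation-product strand.

    Each strand reads, 5'->3':

        left_const | overhang | right_const[:control_offset]
                   | control hexamer | right_const[control_offset:]

    ``control_offset`` is the insertion point of the randomised control
    region within the constant region 3' of the overhang.  The anchor used
    for overhang extraction on the right is ``right_const[:control_offset]``.
    ``control_base_probs``, if given, skews the per-base composition of the
    control (and is applied position-independently), emulating synthesis
    bias.
    """

    left_const: str = DEFAULT_LEFT_CONST
    right_const: str = DEFAULT_RIGHT_CONST
    control_len: int = 6
    control_offset: int = 10
    control_base_probs: tuple[float, float, float, float] | None = None

    def __post_init__(self):
        self.left_const = clean_dna(self.left_const, name="left_const")
        self.right_const = clean_dna(self.right_const, name="right_const")
        if not self.left_const or not self.right_const:
            raise ValueError("anchors must be nonempty")
        if self.left_const in self.right_const or self.right_const in self.left_const:
            raise ValueError("anchors must not contain each other as substrings")
        if not 4 <= self.control_offset <= len(self.right_const):
            raise ValueError(
                "control_offset must lie within the right constant region "
                f"(4..{len(self.right_const)}), got {self.control_offset}"
            )
        if self.control_base_probs is not None:
            p = np.asarray(self.control_base_probs, dtype=float)
            if p.shape != (4,) or (p < 0).any() or p.sum() <= 0:
                raise ValueError("control_base_probs must be 4 nonnegative values")
            self.control_base_probs = tuple(p / p.sum())

    @property
    def right_anchor(self) -> str:
        return self.right_const[:self.control_offset]

    def build_strand(self, overhang: str, control: str) -> str:
        return (
            self.left_const
            + clean_overhang(overhang)
            + self.right_anchor
            + control
            + self.right_const[self.control_offset:]
        )


@dataclass
class ProductRecord:
    """One ligation product: consensus top and bottom strand sequences."""

    event_id: int
    top_strand: str
    bottom_strand: str


def _random_control(spec: SubstrateSpec, rng: np.random.Generator) -> str:
    p = spec.control_base_probs
    codes = rng.choice(4, size=spec.control_len, p=None if p is None else np.asarray(p))
    return "".join(oh.ALPHABET[c] for c in codes)


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < error_rate)
    for i in hits:
        alternatives = [c for c in oh.ALPHABET if c != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def emit_reads(
    events,
    spec: SubstrateSpec | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
) -> Iterator[ProductRecord]:
    """Emit one product record per sampled event.

    The top strand embeds the top overhang and an independent uniform-random
    (or composition-skewed) control hexamer; the bottom strand likewise.
    Substitution errors are applied uniformly per base at ``error_rate``.
    With ``error_rate=0``, extracting the emitted stream reproduces the
    input count matrix exactly.
    """
    if spec is None:
        spec = SubstrateSpec()
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    rng = np.random.default_rng(seed)
    counts = events.counts
    event_id = 0
    iu, ju = np.nonzero(np.triu(counts))
    for i, j in zip(iu, ju):
        n = counts[i, j] if i != j else counts[i, j] // 2
        for _ in range(int(n)):
            top = spec.build_strand(OVERHANGS[i], _random_control(spec, rng))
            bottom = spec.build_strand(OVERHANGS[j], _random_control(spec, rng))
            yield ProductRecord(
                event_id,
                _apply_errors(top, error_rate, rng),
                _apply_errors(bottom, error_rate, rng),
            )
            event_id += 1


def write_products_fasta(records, path) -> int:
    """Write product records as FASTA, two records per event.

    Record IDs are ``<event>#top`` and ``<event>#bottom``, the pairing
    convention the extractor expects.  Returns the number of events written.
    """
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.event_id}#top\n{rec.top_strand}\n")
            fh.write(f">{rec.event_id}#bottom\n{rec.bottom_strand}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Model configuration files and illustrative presets.

def load_model(path) -> LigaseModel:
    """Read a :class:`LigaseModel` from a flat YAML key-value file.

    Recognised keys: ``name``, ``anneal_coeff``, ``weights`` (mapping
    overhang -> weight) and ``tolerances`` (mapping "G:T@edge" -> value).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"model config {path} must be a mapping")
    tol = {}
    for key, value in (cfg.get("tolerances") or {}).items():
        label, _, cls = str(key).partition("@")
        tol[(label, cls)] = float(value)
    return LigaseModel(
        name=str(cfg.get("name", "unnamed")),
        weights=cfg.get("weights") or {},
        anneal_coeff=float(cfg.get("anneal_coeff", 0.0)),
        mismatch_tolerance=tol,
        mismatch_anneal_coeff=float(cfg.get("mismatch_anneal_coeff", 0.0)),
    )


def save_model(model: LigaseModel, path) -> None:
    cfg = {
        "name": model.name,
        "anneal_coeff": model.anneal_coeff,
        "mismatch_anneal_coeff": model.mismatch_anneal_coeff,
        "weights": dict(model.weights),
        "tolerances": {f"{t}@{c}": v for (t, c), v in model.mismatch_tolerance.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def preset_model(name: str) -> LigaseModel:
    """Illustrative model presets.

    These sketch qualitative regimes (a strongly GC-biased, stringent ligase
    versus a bias-free, mismatch-permissive one); they are not fitted to any
    measured enzyme.
    """
    if name == "uniform":
        return LigaseModel(name="uniform")
    if name == "gc-biased-strict":
        return LigaseModel(
            name="gc-biased-strict",
            anneal_coeff=0.8,
            mismatch_tolerance={("G:T", "edge"): 0.02},
        )
    if name == "permissive":
        return LigaseModel(
            name="permissive",
            anneal_coeff=0.15,
            mismatch_anneal_coeff=0.2,
            mismatch_tolerance={
                ("G:T", "edge"): 0.30,
                ("G:T", "middle"): 0.08,
                ("G:A", "edge"): 0.15,
                ("G:G", "edge"): 0.12,
                ("C:T", "edge"): 0.05,
                ("A:A", "edge"): 0.04,
                ("G:A", "middle"): 0.04,
            },
        )
    raise ValueError(f"unknown preset {name!r}; choose uniform, gc-biased-strict, permissive")
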