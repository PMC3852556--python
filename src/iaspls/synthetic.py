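"""Seeded generators for benchmark data.

Two families of fixtures:

* sparse linear classification data (few informative columns among many
  noise columns) for exercising the numerical core, and
* coding-like vs. noncoding-like DNA sequences (biased codon usage,
  start codon, in-frame structure vs. iid background bases) for
  exercising the full pipeline without any external download.

Everything is fully determined by the spec's seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import DataError
from .features import CODONS, STOP_CODONS
from .seqio import ACGT, DnaSequence

logger = logging.getLogger(__name__)

_MAX_RESAMPLE = 20


# ---------------------------------------------------------------------------
# sparse linear classification data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SparseLinearSpec:
    """Parameters for the sparse linear classification generator."""

    n: int
    p: int
    n_informative: int
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DataError("need at least 2 samples")
        if not 1 <= self.n_informative <= self.p:
            raise DataError("n_informative must be in [1, p]")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be nonnegative")


def generate_sparse_linear_data(
    spec: SparseLinearSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate (X, y, informative_indices).

    X is iid standard normal; the latent score is
    ``effect_size * sum of the informative columns + N(0, noise_sd)``
    and ``y = sign(score)`` (zero scores go to +1). If thresholding
    leaves one class empty the noise is redrawn (bounded retries,
    logged).
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n, spec.p))
    informative = rng.choice(spec.p, size=spec.n_informative, replace=False)
    informative.sort()
    signal = spec.effect_size * X[:, informative].sum(axis=1)
    for attempt in range(_MAX_RESAMPLE):
        noise = rng.normal(0.0, spec.noise_sd, size=spec.n) if spec.noise_sd > 0 else 0.0
        y = np.where(signal + noise >= 0.0, 1, -1)
        if len(np.unique(y)) == 2:
            if attempt:
                logger.warning("resampled noise %d time(s) to get both classes", attempt)
            return X, y, informative
    raise DataError(
        "could not generate both classes; the spec is degenerate "
        "(effect/noise leave one class empty)"
    )


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def uniform_background() -> dict[str, float]:
    return {b: 0.25 for b in ACGT}


def gc_biased_codon_usage(gc_prob: float = 0.4) -> dict[str, float]:
    """Codon distribution implied by iid bases with P(C) = P(G) = *gc_prob*.

    A convenient strongly GC-biased table for benchmark contrasts with a
    uniform background.
    """
    if not 0 < gc_prob < 0.5:
        raise DataError("gc_prob must be in (0, 0.5)")
    base_p = {"A": 0.5 - gc_prob, "C": gc_prob, "G": gc_prob, "T": 0.5 - gc_prob}
    usage = {c: base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in CODONS}
    total = sum(usage.values())
    return {c: v / total for c, v in usage.items()}


def codon_usage_from_background(background: Mapping[str, float]) -> dict[str, float]:
    """The codon distribution implied by iid draws from *background*.

    Used to build matched (no-signal) null benchmarks.
    """
    probs = _normalize_base_probs(background)
    usage = {c: probs[c[0]] * probs[c[1]] * probs[c[2]] for c in CODONS}
    return usage


def _normalize_base_probs(background: Mapping[str, float]) -> dict[str, float]:
    probs = {b: float(background.get(b, 0.0)) for b in ACGT}
    total = sum(probs.values())
    if total <= 0 or any(v < 0 for v in probs.values()):
        raise DataError("background composition must be nonnegative with positive sum")
    return {b: v / total for b, v in probs.items()}


def _normalize_codon_usage(usage: Mapping[str, float]) -> dict[str, float]:
    probs = {c: float(usage.get(c, 0.0)) for c in CODONS}
    total = sum(probs.values())
    if total <= 0 or any(v < 0 for v in probs.values()):
        raise DataError("codon usage must be nonnegative with positive sum")
    return {c: v / total for c, v in probs.items()}


@dataclass(frozen=True)
class SequenceSimSpec:
    """Parameters for the coding-like vs. noncoding-like generator.

    With ``coding_structure`` (default), coding-like sequences start
    with ATG, have length a multiple of 3, and exclude in-frame stop
    codons. Disabling it produces iid codon draws with no enforced
    structure — useful for matched-null experiments where the codon
    table equals the background's implied codon distribution.
    """

    n_coding: int
    n_noncoding: int
    length_range: tuple[int, int] = (60, 400)
    codon_usage: Mapping[str, float] | None = None
    background_composition: Mapping[str, float] | None = None
    seed: int = 0
    coding_structure: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if hi < lo:
            raise DataError("length_range out of order")
        if hi < 60 or lo < 60 or hi > 400:
            raise DataError("length_range must lie within [60, 400]")
        if self.n_coding < 0 or self.n_noncoding < 0:
            raise DataError("sequence counts must be nonnegative")


def generate_sequence_dataset(
    spec: SequenceSimSpec,
) -> tuple[list[DnaSequence], dict]:
    """Generate labeled sequences plus a spec echo for reproducibility.

    Coding-like sequences (label +1): length drawn uniformly in range
    and rounded down to a multiple of 3, a leading ATG, remaining codons
    iid from ``codon_usage`` with in-frame stops excluded (when
    ``coding_structure``). Noncoding-like sequences (label -1): iid
    bases from ``background_composition`` at any length in range.
    """
    rng = np.random.default_rng(spec.seed)
    usage = _normalize_codon_usage(
        spec.codon_usage if spec.codon_usage is not None else gc_biased_codon_usage()
    )
    background = _normalize_base_probs(
        spec.background_composition
        if spec.background_composition is not None
        else uniform_background()
    )

    codons = list(CODONS)
    codon_p = np.array([usage[c] for c in codons])
    if spec.coding_structure:
        keep = np.array([c not in STOP_CODONS for c in codons])
        if codon_p[keep].sum() <= 0:
            raise DataError("codon usage puts all mass on stop codons")
        codon_p = np.where(keep, codon_p, 0.0)
    codon_p = codon_p / codon_p.sum()

    lo, hi = spec.length_range
    seqs: list[DnaSequence] = []
    for i in range(spec.n_coding):
        length = int(rng.integers(lo, hi + 1))
        length -= length % 3
        if length < lo:  # keep within range after rounding
            length += 3
            if length > hi:
                raise DataError(
                    f"no multiple-of-3 length inside range [{lo}, {hi}]"
                )
        n_codons = length // 3
        drawn = rng.choice(len(codons), size=n_codons, p=codon_p)
        parts = [codons[j] for j in drawn]
        if spec.coding_structure:
            parts[0] = "ATG"
        seqs.append(DnaSequence(f"coding_{i:05d}", "".join(parts), label=1))

    base_p = np.array([background[b] for b in ACGT])
    for i in range(spec.n_noncoding):
        length = int(rng.integers(lo, hi + 1))
        drawn = rng.choice(4, size=length, p=base_p)
        seqs.append(
            DnaSequence(
                f"noncoding_{i:05d}", "".join(ACGT[j] for j in drawn), label=-1
            )
        )

    echo = {
        "n_coding": spec.n_coding,
        "n_noncoding": spec.n_noncoding,
        "length_range": list(spec.length_range),
        "codon_usage": usage,
        "background_composition": background,
        "seed": spec.seed,
        "coding_structure": spec.coding_structure,
    }
    return seqs, echo


def write_spec_echo(echo: dict, path: str | Path) -> None:
    """Write the generator's resolved parameters as JSON."""
    with open(path, "w") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True)


def load_sim_spec(path: str | Path) -> SequenceSimSpec:
    """Read a :class:`SequenceSimSpec` from a JSON file."""
    with open(path) as fh:
        payload = json.load(fh)
    try:
        return SequenceSimSpec(
            n_coding=int(payload["n_coding"]),
            n_noncoding=int(payload["n_noncoding"]),
            length_range=tuple(payload.get("length_range", (60, 400))),
            codon_usage=payload.get("codon_usage"),
            background_composition=payload.get("background_composition"),
            seed=int(payload.get("seed", 0)),
            coding_structure=bool(payload.get("coding_structure", True)),
        )
    except KeyError as exc:
        raise DataError(f"simulation spec missing required key: {exc}") from exc
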