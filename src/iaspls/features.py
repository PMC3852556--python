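"""DNA feature catalogue: fixed-order numeric vectors for short sequences.

Seven feature blocks are supported, concatenated in a fixed documented
order:

========== ===== =======================================================
block      width contents
========== ===== =======================================================
zcurve       252 Z-transform triples of k-mer frequencies, k = 1..3,
                 once phase-independently (63) and once per codon
                 phase 0/1/2 (3 x 63)
kmer          84 overlapping k-mer frequencies, k = 1..3 (4 + 16 + 64)
gc_cai         3 GC content, Fop (frequency of optimal codons), CAI
gc3s           4 base composition at third codon positions
aa_props       2 mean hydropathy and aromatic fraction of translation
rho           16 dinucleotide odds ratios f(XY) / (f_X * f_Y)
dinuc_props   65 mean dinucleotide property values (default table)
========== ===== =======================================================

Total width with all blocks and default tables: **426**. The width of
the ``dinuc_props`` block follows the property table in use; every
block's width is exposed via :func:`block_widths`.

Windows containing ambiguity codes are skipped and the corresponding
denominator reduced; ambiguous characters are never mapped to a base.
Codons are always read in frame 0 from the first base, and a trailing
partial codon is dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .errors import DataError
from .seqio import ACGT, DnaSequence

logger = logging.getLogger(__name__)

#: All 64 codons in lexicographic order (A < C < G < T).
CODONS: tuple[str, ...] = tuple("".join(c) for c in product(ACGT, repeat=3))

#: Standard-code stop codons (identical in the bacterial code).
STOP_CODONS: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})

#: codon -> one-letter amino acid, stops excluded.
GENETIC_CODE: dict[str, str] = dict(unambiguous_dna_by_id[11].forward_table)

#: Amino acids encoded by a single codon; excluded from CAI by convention.
SINGLE_CODON_AAS: frozenset[str] = frozenset({"M", "W"})

AROMATIC_AAS = frozenset("FWY")

#: Fixed block order used when concatenating feature vectors.
BLOCK_ORDER: tuple[str, ...] = (
    "zcurve",
    "kmer",
    "gc_cai",
    "gc3s",
    "aa_props",
    "rho",
    "dinuc_props",
)


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("iaspls").joinpath("data", name)))


def load_dinucleotide_properties(path: str | Path | None = None) -> pd.DataFrame:
    """Load a dinucleotide property table (16 rows x m property columns).

    The file is tab-separated with a ``dinucleotide`` index column. The
    shipped default provides 16 physicochemical and 49 conformational
    property columns (65 total).
    """
    if path is None:
        path = _data_path("dinucleotide_properties.tsv")
    table = pd.read_csv(path, sep="\t", comment=None, index_col=0)
    table.index = table.index.str.upper()
    _check_property_table(table)
    return table


def _check_property_table(table: pd.DataFrame) -> None:
    wanted = ["".join(d) for d in product(ACGT, repeat=2)]
    missing = [d for d in wanted if d not in table.index]
    if missing:
        raise DataError(f"property table missing dinucleotides: {missing}")
    if table.shape[1] < 1:
        raise DataError("property table has no property columns")
    if not np.isfinite(table.loc[wanted].to_numpy(dtype=float)).all():
        raise DataError("property table contains non-finite values")


def load_codon_usage(path: str | Path | None = None) -> dict[str, float]:
    """Load a codon usage table as a normalized 64-entry probability dict.

    The file is two-column tab-separated (codon, weight); weights are
    normalized to sum to one. The shipped default is an E. coli-like
    usage table.
    """
    if path is None:
        path = _data_path("codon_usage_ecoli_like.tsv")
    usage: dict[str, float] = {c: 0.0 for c in CODONS}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected two columns")
            codon, raw = parts[0].upper(), parts[1]
            if codon not in usage:
                raise DataError(f"{path}:{lineno}: invalid codon {codon!r}")
            usage[codon] = float(raw)
    total = sum(usage.values())
    if total <= 0:
        raise DataError(f"codon usage table {path} sums to zero")
    return {c: v / total for c, v in usage.items()}


@dataclass(frozen=True)
class CodonReference:
    """Relative adaptiveness values and optimal-codon set for CAI / Fop.

    ``w`` maps non-stop codons to relative adaptiveness in (0, 1] with
    the best codon of each amino-acid family at 1. ``optimal`` is the
    set of optimal codons (one per family with usable counts).
    Families with zero total count are excluded from both.
    """

    w: Mapping[str, float]
    optimal: frozenset[str]

    def __post_init__(self) -> None:
        for codon, value in self.w.items():
            if codon not in GENETIC_CODE:
                raise DataError(f"reference defines w for invalid codon {codon!r}")
            if not 0.0 < value <= 1.0:
                raise DataError(f"w({codon}) = {value} outside (0, 1]")
        if not set(self.optimal) <= set(self.w):
            raise DataError("optimal codons must have w values")

    @property
    def fop_amino_acids(self) -> frozenset[str]:
        """Amino acids that have a designated optimal codon."""
        return frozenset(GENETIC_CODE[c] for c in self.optimal)

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, float], floor: float = 0.01
    ) -> "CodonReference":
        """Build relative adaptiveness from raw codon counts.

        Within each amino-acid family, ``w = count / max(count)``; the
        argmax codon (lexicographically first on ties) is optimal.
        Codons with zero count get the conventional floor ``w`` so the
        geometric mean stays defined. Zero-count families are excluded
        (logged).
        """
        families: dict[str, list[str]] = {}
        for codon, aa in GENETIC_CODE.items():
            families.setdefault(aa, []).append(codon)
        w: dict[str, float] = {}
        optimal: set[str] = set()
        for aa, codons in sorted(families.items()):
            codons = sorted(codons)
            family_counts = [float(counts.get(c, 0.0)) for c in codons]
            peak = max(family_counts)
            if peak <= 0:
                logger.warning("codon family %s has zero counts; excluded", aa)
                continue
            for codon, c in zip(codons, family_counts):
                w[codon] = max(c / peak, floor)
            optimal.add(codons[int(np.argmax(family_counts))])
        if not w:
            raise DataError("codon counts empty: cannot build a reference")
        return cls(w=w, optimal=frozenset(optimal))

    @classmethod
    def from_sequences(cls, seqs: Iterable[DnaSequence]) -> "CodonReference":
        """Build a reference from the codon counts of training sequences."""
        counts: dict[str, int] = {c: 0 for c in CODONS}
        for s in seqs:
            for codon in _complete_codons(s.bases):
                counts[codon] += 1
        return cls.from_counts(counts)

    @classmethod
    def load(cls, path: str | Path) -> "CodonReference":
        """Load from a tab-separated file: codon, w, optional ``optimal`` flag."""
        w: dict[str, float] = {}
        optimal: set[str] = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) not in (2, 3):
                    raise DataError(f"{path}:{lineno}: expected 2 or 3 columns")
                codon = parts[0].upper()
                w[codon] = float(parts[1])
                if len(parts) == 3 and parts[2].lower() in ("1", "optimal", "true"):
                    optimal.add(codon)
        return cls(w=w, optimal=frozenset(optimal))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# codon\tw\toptimal\n")
            for codon in sorted(self.w):
                flag = "1" if codon in self.optimal else "0"
                fh.write(f"{codon}\t{self.w[codon]:.6f}\t{flag}\n")


def default_codon_reference() -> CodonReference:
    """Reference derived from the shipped E. coli-like usage table."""
    usage = load_codon_usage()
    return CodonReference.from_counts({c: v * 1000.0 for c, v in usage.items()})


# ---------------------------------------------------------------------------
# per-sequence feature blocks
# ---------------------------------------------------------------------------

def _kmer_index(kmer: str) -> int:
    idx = 0
    for b in kmer:
        idx = idx * 4 + ACGT.index(b)
    return idx


def _count_kmers(bases: str, k: int, phase: int | None = None) -> np.ndarray:
    """Counts of overlapping k-mers in lexicographic order.

    Windows containing non-ACGT characters are skipped. With *phase*
    given, only windows starting at positions ``i`` with ``i % 3 ==
    phase`` are counted.
    """
    counts = np.zeros(4 ** k)
    step = 1 if phase is None else 3
    start = 0 if phase is None else phase
    for i in range(start, len(bases) - k + 1, step):
        window = bases[i : i + k]
        if all(b in ACGT for b in window):
            counts[_kmer_index(window)] += 1
    return counts


def kmer_frequencies(seq: DnaSequence, k: int) -> np.ndarray:
    """Overlapping k-mer frequencies (length ``4**k``), summing to one.

    Windows containing ambiguity codes are skipped and the denominator
    reduced accordingly.
    """
    if k not in (1, 2, 3):
        raise DataError(f"k must be in {{1, 2, 3}}, got {k}")
    counts = _count_kmers(seq.bases, k)
    total = counts.sum()
    if total == 0:
        raise DataError(f"sequence {seq.id!r}: no valid {k}-mer window")
    return counts / total


def kmer_feature_names() -> list[str]:
    return [
        f"kmer:{''.join(m)}" for k in (1, 2, 3) for m in product(ACGT, repeat=k)
    ]


def _zcurve_triples(counts: np.ndarray, k: int) -> np.ndarray:
    """Z-transform triples (x, y, z) per conditioning prefix.

    Frequencies are normalized within each length-(k-1) prefix; a
    prefix with zero observed windows yields (0, 0, 0).
    """
    rows = counts.reshape(4 ** (k - 1), 4)
    totals = rows.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(totals > 0, rows / np.where(totals > 0, totals, 1.0), 0.0)
    fa, fc, fg, ft = f[:, 0], f[:, 1], f[:, 2], f[:, 3]
    x = (fa + fg) - (fc + ft)
    y = (fa + fc) - (fg + ft)
    z = (fa + ft) - (fg + fc)
    return np.column_stack([x, y, z]).ravel()


#: (tag, phase) pairs defining the Z-curve variant order.
_ZCURVE_VARIANTS: tuple[tuple[str, int | None], ...] = (
    ("g", None),
    ("p0", 0),
    ("p1", 1),
    ("p2", 2),
)


def zcurve_features(seq: DnaSequence) -> np.ndarray:
    """The 252 Z-curve components of a sequence.

    For k = 1..3 the Z-transform triples of within-prefix k-mer
    frequencies are computed once phase-independently (3 + 12 + 48 = 63
    values) and once per codon phase 0/1/2 (189 values), for 252 in
    total. All components lie in [-1, 1].
    """
    if len(seq) < 3 or _count_kmers(seq.bases, 3).sum() == 0:
        raise DataError(f"sequence {seq.id!r}: no valid codon-length window")
    parts = []
    for _tag, phase in _ZCURVE_VARIANTS:
        for k in (1, 2, 3):
            parts.append(_zcurve_triples(_count_kmers(seq.bases, k, phase), k))
    return np.concatenate(parts)


def zcurve_feature_names() -> list[str]:
    names = []
    for tag, _phase in _ZCURVE_VARIANTS:
        for k in (1, 2, 3):
            prefixes = ["".join(p) for p in product(ACGT, repeat=k - 1)] or [""]
            for prefix in prefixes:
                for comp in "xyz":
                    names.append(f"zcurve:{tag}:k{k}:{prefix}:{comp}")
    return names


def gc_content(seq: DnaSequence) -> float:
    """(#G + #C) / (#A + #C + #G + #T); ambiguous bases excluded."""
    counts = _count_kmers(seq.bases, 1)
    total = counts.sum()
    if total == 0:
        raise DataError(f"sequence {seq.id!r}: no unambiguous base")
    return float((counts[1] + counts[2]) / total)


def _complete_codons(bases: str, skip_ambiguous: bool = True) -> list[str]:
    codons = [bases[i : i + 3] for i in range(0, len(bases) - 2, 3)]
    if skip_ambiguous:
        codons = [c for c in codons if all(b in ACGT for b in c)]
    return codons


def gc3s_composition(seq: DnaSequence) -> np.ndarray:
    """Base composition (A, C, G, T order) at third codon positions.

    Frame 0, trailing partial codon ignored; codons with an ambiguous
    third base are skipped.
    """
    thirds = [
        seq.bases[i + 2]
        for i in range(0, len(seq.bases) - 2, 3)
        if seq.bases[i + 2] in ACGT
    ]
    if not thirds:
        raise DataError(f"sequence {seq.id!r}: no complete codon for GC3s")
    counts = np.zeros(4)
    for b in thirds:
        counts[ACGT.index(b)] += 1
    return counts / counts.sum()


def codon_usage_indices(
    seq: DnaSequence, reference: CodonReference
) -> tuple[float, float]:
    """(Fop, CAI) of a sequence under *reference*.

    Fop is the fraction of optimal codons among codons whose amino-acid
    family has a designated optimal codon. CAI is the geometric mean of
    relative adaptiveness over codons, excluding stop codons and
    single-codon amino acids (M, W). If no codon remains for CAI after
    the standard exclusions, the single-codon families are re-admitted
    (they carry w = 1 whenever defined); a zero Fop denominator yields
    Fop = 0 by convention (logged).
    """
    if reference is None:
        raise DataError("codon usage indices require a codon reference")
    codons = [c for c in _complete_codons(seq.bases) if c not in STOP_CODONS]
    codons = [c for c in codons if c in reference.w]
    if not codons:
        raise DataError(f"sequence {seq.id!r}: no countable codon")

    fop_aas = reference.fop_amino_acids
    fop_den = sum(1 for c in codons if GENETIC_CODE[c] in fop_aas)
    if fop_den == 0:
        logger.warning("sequence %r: Fop denominator empty; Fop = 0", seq.id)
        fop = 0.0
    else:
        fop = sum(1 for c in codons if c in reference.optimal) / fop_den

    cai_codons = [c for c in codons if GENETIC_CODE[c] not in SINGLE_CODON_AAS]
    if not cai_codons:
        cai_codons = codons
    log_sum = sum(math.log(reference.w[c]) for c in cai_codons)
    cai = math.exp(log_sum / len(cai_codons))
    return fop, cai


def protein_properties(
    seq: DnaSequence, scale: Mapping[str, float] | None = None
) -> tuple[float, float]:
    """(hydrophobicity, aromaticity) of the frame-0 translation.

    Complete unambiguous codons are translated with the bacterial code;
    stop codons are skipped, not truncating. Hydrophobicity is the mean
    per-residue value of *scale* (default Kyte-Doolittle hydropathy);
    aromaticity is the fraction of residues in {F, W, Y}.
    """
    if scale is None:
        scale = KYTE_DOOLITTLE
    residues = [
        GENETIC_CODE[c]
        for c in _complete_codons(seq.bases)
        if c not in STOP_CODONS
    ]
    if not residues:
        raise DataError(f"sequence {seq.id!r}: translation yields no residue")
    hydro = float(np.mean([scale[aa] for aa in residues]))
    arom = sum(1 for aa in residues if aa in AROMATIC_AAS) / len(residues)
    return hydro, arom


def rho_statistic(seq: DnaSequence) -> np.ndarray:
    """Dinucleotide odds ratios rho_XY = f(XY) / (f_X * f_Y), length 16.

    Lexicographic dinucleotide order; entries with a zero mononucleotide
    product are 0 by convention.
    """
    mono = _count_kmers(seq.bases, 1)
    if mono.sum() == 0:
        raise DataError(f"sequence {seq.id!r}: no unambiguous base")
    f_mono = mono / mono.sum()
    di = _count_kmers(seq.bases, 2)
    if di.sum() == 0:
        raise DataError(f"sequence {seq.id!r}: no valid dinucleotide window")
    f_di = di / di.sum()
    rho = np.zeros(16)
    for i in range(4):
        for j in range(4):
            denom = f_mono[i] * f_mono[j]
            if denom > 0:
                rho[i * 4 + j] = f_di[i * 4 + j] / denom
    return rho


def dinucleotide_property_profile(
    seq: DnaSequence, table: pd.DataFrame
) -> np.ndarray:
    """Mean property values over overlapping dinucleotide windows.

    *table* is indexed by the 16 dinucleotides with one column per
    property; the result has one entry per property column.
    """
    _check_property_table(table)
    di = _count_kmers(seq.bases, 2)
    total = di.sum()
    if total == 0:
        raise DataError(f"sequence {seq.id!r}: no valid dinucleotide window")
    dinucs = ["".join(d) for d in product(ACGT, repeat=2)]
    values = table.loc[dinucs].to_numpy(dtype=float)
    return (di / total) @ values


# ---------------------------------------------------------------------------
# feature matrix assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureConfig:
    """Which feature blocks to compute, plus their auxiliary tables.

    If ``codon_reference`` is ``None`` and the ``gc_cai`` block is
    enabled, the reference is built from the codon counts of the
    positive (label +1) input sequences, falling back to the shipped
    E. coli-like table when no labeled positives are available.
    """

    enabled_blocks: tuple[str, ...] = BLOCK_ORDER
    codon_reference: CodonReference | None = None
    property_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        unknown = set(self.enabled_blocks) - set(BLOCK_ORDER)
        if unknown:
            raise DataError(f"unknown feature blocks: {sorted(unknown)}")
        if not self.enabled_blocks:
            raise DataError("at least one feature block must be enabled")
        # canonical order regardless of how the caller listed the blocks
        ordered = tuple(b for b in BLOCK_ORDER if b in self.enabled_blocks)
        object.__setattr__(self, "enabled_blocks", ordered)

    def resolved_property_table(self) -> pd.DataFrame:
        if self.property_table is not None:
            _check_property_table(self.property_table)
            return self.property_table
        return load_dinucleotide_properties()

    def resolve_reference(self, seqs: Sequence[DnaSequence]) -> CodonReference:
        if self.codon_reference is not None:
            return self.codon_reference
        positives = [s for s in seqs if s.label == 1]
        if positives:
            return CodonReference.from_sequences(positives)
        return default_codon_reference()


def block_widths(config: FeatureConfig) -> dict[str, int]:
    """Width of each enabled block under *config*."""
    widths = {
        "zcurve": 252,
        "kmer": 84,
        "gc_cai": 3,
        "gc3s": 4,
        "aa_props": 2,
        "rho": 16,
    }
    out = {}
    for block in config.enabled_blocks:
        if block == "dinuc_props":
            out[block] = int(config.resolved_property_table().shape[1])
        else:
            out[block] = widths[block]
    return out


def feature_names(config: FeatureConfig) -> list[str]:
    """Ordered column names; a pure function of the configuration."""
    names: list[str] = []
    for block in config.enabled_blocks:
        if block == "zcurve":
            names.extend(zcurve_feature_names())
        elif block == "kmer":
            names.extend(kmer_feature_names())
        elif block == "gc_cai":
            names.extend(["gc_content", "fop", "cai"])
        elif block == "gc3s":
            names.extend([f"gc3s:{b}" for b in ACGT])
        elif block == "aa_props":
            names.extend(["hydrophobicity", "aromaticity"])
        elif block == "rho":
            names.extend(
                [f"rho:{''.join(d)}" for d in product(ACGT, repeat=2)]
            )
        elif block == "dinuc_props":
            names.extend(
                [f"dinuc:{c}" for c in config.resolved_property_table().columns]
            )
    return names


@dataclass
class FeatureMatrix:
    """An n x p numeric matrix with named, ordered columns and row ids."""

    values: np.ndarray
    column_names: list[str]
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("feature matrix must be two-dimensional")
        if self.values.shape != (len(self.row_ids), len(self.column_names)):
            raise DataError("feature matrix shape does not match names/ids")
        if not np.isfinite(self.values).all():
            raise DataError("feature matrix contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, columns=self.column_names)
        frame.insert(0, "id", self.row_ids)
        frame.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t")
        if frame.columns[0] != "id":
            raise DataError(f"{path}: first column must be 'id'")
        return cls(
            values=frame.iloc[:, 1:].to_numpy(dtype=float),
            column_names=list(frame.columns[1:]),
            row_ids=[str(x) for x in frame["id"]],
        )


def _sequence_features(
    seq: DnaSequence,
    config: FeatureConfig,
    reference: CodonReference | None,
    table: pd.DataFrame | None,
) -> np.ndarray:
    parts: list[np.ndarray] = []
    for block in config.enabled_blocks:
        try:
            if block == "zcurve":
                parts.append(zcurve_features(seq))
            elif block == "kmer":
                parts.append(
                    np.concatenate([kmer_frequencies(seq, k) for k in (1, 2, 3)])
                )
            elif block == "gc_cai":
                fop, cai = codon_usage_indices(seq, reference)
                parts.append(np.array([gc_content(seq), fop, cai]))
            elif block == "gc3s":
                parts.append(gc3s_composition(seq))
            elif block == "aa_props":
                parts.append(np.array(protein_properties(seq)))
            elif block == "rho":
                parts.append(rho_statistic(seq))
            elif block == "dinuc_props":
                parts.append(dinucleotide_property_profile(seq, table))
        except DataError as exc:
            raise DataError(
                f"feature extraction failed for sequence {seq.id!r} "
                f"in block {block!r}: {exc}"
            ) from exc
    return np.concatenate(parts)


def build_feature_matrix(
    seqs: Sequence[DnaSequence], config: FeatureConfig | None = None
) -> FeatureMatrix:
    """Transform sequences into a :class:`FeatureMatrix`.

    Rows follow input order; columns are concatenated block-by-block in
    the order of :data:`BLOCK_ORDER`. Deterministic: the same inputs
    produce a bit-identical matrix.
    """
    if config is None:
        config = FeatureConfig()
    if not seqs:
        raise DataError("cannot build a feature matrix from zero sequences")
    reference = (
        config.resolve_reference(seqs) if "gc_cai" in config.enabled_blocks else None
    )
    table = (
        config.resolved_property_table()
        if "dinuc_props" in config.enabled_blocks
        else None
    )
    rows = [_sequence_features(s, config, reference, table) for s in seqs]
    return FeatureMatrix(
        values=np.vstack(rows),
        column_names=feature_names(
            replace(config, property_table=table) if table is not None else config
        ),
        row_ids=[s.id for s in seqs],
    )
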