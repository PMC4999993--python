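"""Biophysical feature extraction for protein sequences.

A sequence is encoded as a fixed-layout vector of 258 scalars organised in 14
named feature groups covering amino-acid composition, physicochemical
summaries, predicted secondary structure, transmembrane helices, intrinsic
disorder, signal peptides, low-complexity regions, short functional motifs,
coiled coils, hydrophobic moments, charge patterning and sequence
autocorrelation.  All extractors are fast, deterministic, propensity-scale
approximations of the structure-prediction tools normally used for this kind
of encoding; :func:`register_external_group` swaps any group for a lookup
table of externally computed values when higher fidelity is needed.

The per-group layout is the contract the classifiers rely on: group names are
unique, the order is fixed, and composition-type groups sum to one.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .errors import LookupError_, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

MIN_LENGTH = 15

# --- residue property scales -----------------------------------------------

# Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# TOP-IDP disorder propensity (Campen et al.); positive = disorder-promoting
TOP_IDP = {
    "A": 0.06, "R": 0.180, "N": 0.007, "D": 0.192, "C": 0.02,
    "Q": 0.318, "E": 0.736, "G": 0.166, "H": 0.303, "I": -0.486,
    "L": -0.326, "K": 0.586, "M": -0.397, "F": -0.697, "P": 0.987,
    "S": 0.341, "T": 0.059, "W": -0.884, "Y": -0.510, "V": -0.121,
}

# Chou-Fasman helix / sheet propensities
CF_HELIX = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70, "Q": 1.11,
    "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08, "L": 1.21, "K": 1.16,
    "M": 1.45, "F": 1.13, "P": 0.57, "S": 0.77, "T": 0.83, "W": 1.08,
    "Y": 0.69, "V": 1.06,
}
CF_SHEET = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.10,
    "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60, "L": 1.30, "K": 0.74,
    "M": 1.05, "F": 1.38, "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37,
    "Y": 1.47, "V": 1.70,
}

# Zimmerman bulkiness
BULKINESS = {
    "A": 11.50, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46,
    "Q": 14.45, "E": 13.57, "G": 3.40, "H": 13.69, "I": 21.40,
    "L": 21.40, "K": 15.71, "M": 16.25, "F": 19.80, "P": 17.43,
    "S": 9.47, "T": 15.77, "W": 21.67, "Y": 18.03, "V": 21.57,
}

# Grantham polarity
POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}

# Vihinen flexibility (average)
FLEXIBILITY = {
    "A": 0.984, "R": 1.008, "N": 1.048, "D": 1.068, "C": 0.906,
    "Q": 1.037, "E": 1.094, "G": 1.031, "H": 0.950, "I": 0.927,
    "L": 0.935, "K": 1.102, "M": 0.952, "F": 0.915, "P": 1.049,
    "S": 1.046, "T": 0.997, "W": 0.904, "Y": 0.929, "V": 0.931,
}

CHARGE = {aa: 0.0 for aa in AMINO_ACIDS}
CHARGE.update({"K": 1.0, "R": 1.0, "H": 0.5, "D": -1.0, "E": -1.0})

# seven physicochemical residue classes (conjoint-triad style)
RESIDUE_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")
_CLASS_OF = {aa: ci for ci, cls in enumerate(RESIDUE_CLASSES) for aa in cls}

POSITIVE = set("KR")
NEGATIVE = set("DE")

# default window sizes (residues)
TM_WINDOW = 21
TM_THRESHOLD = 1.6          # mean Kyte-Doolittle over the window
DISORDER_WINDOW = 15
LOWCOMP_WINDOW = 12
LOWCOMP_ENTROPY = 2.2       # bits; windows below are low-complexity
HM_WINDOW = 11
CC_WINDOW = 28


def _scale_array(scale: Mapping[str, float]) -> np.ndarray:
    return np.array([scale[aa] for aa in AMINO_ACIDS])


def _encode(seq: str, scale: Mapping[str, float]) -> np.ndarray:
    arr = _scale_array(scale)
    idx = np.fromiter((_AA_INDEX[a] for a in seq), dtype=np.intp, count=len(seq))
    return arr[idx]


def _window_means(x: np.ndarray, w: int) -> np.ndarray:
    """Mean of each length-w window; empty when the sequence is shorter."""
    if len(x) < w:
        return np.empty(0)
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[w:] - c[:-w]) / w


def _runs(mask: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True."""
    runs, n = [], 0
    for v in mask:
        if v:
            n += 1
        elif n:
            runs.append(n)
            n = 0
    if n:
        runs.append(n)
    return runs


# --- group extractors -------------------------------------------------------


def _composition(seq: str) -> np.ndarray:
    counts = np.zeros(20)
    for aa in seq:
        counts[_AA_INDEX[aa]] += 1
    return counts / len(seq)


def _class_pair_composition(seq: str) -> np.ndarray:
    counts = np.zeros((7, 7))
    for a, b in zip(seq, seq[1:]):
        counts[_CLASS_OF[a], _CLASS_OF[b]] += 1
    total = counts.sum()
    if total:
        counts /= total
    return counts.ravel()


def _global_properties(seq: str) -> np.ndarray:
    pa = ProteinAnalysis(seq)
    n = len(seq)
    ext_red, _ext_ox = pa.molar_extinction_coefficient()
    return np.array([
        n,
        math.log10(n),
        pa.molecular_weight() / n,
        pa.gravy(),
        pa.charge_at_pH(7.0) / n,
        pa.isoelectric_point(),
        pa.aromaticity(),
        pa.instability_index(),
        ext_red / n,
    ])


def _secondary_structure(seq: str) -> np.ndarray:
    """Windowed Chou-Fasman state assignment: per-residue helix and sheet
    propensities smoothed over 7 residues; state = argmax(helix, sheet, 1)."""
    h = _window_means(_encode(seq, CF_HELIX), 7)
    s = _window_means(_encode(seq, CF_SHEET), 7)
    n = len(seq)
    if h.size == 0:
        h = np.array([np.mean(_encode(seq, CF_HELIX))])
        s = np.array([np.mean(_encode(seq, CF_SHEET))])
    helix = (h > 1.0) & (h >= s)
    sheet = (s > 1.0) & (s > h)
    nh, ns = int(helix.sum()), int(sheet.sum())
    m = len(helix)
    h_runs, s_runs = _runs(helix), _runs(sheet)
    return np.array([
        nh / m,
        ns / m,
        1.0 - (nh + ns) / m,
        (max(h_runs) / n) if h_runs else 0.0,
        (max(s_runs) / n) if s_runs else 0.0,
        len(h_runs) / n * 100,
        len(s_runs) / n * 100,
        float(np.mean(h) - np.mean(s)),
    ])


def _tm_segments(seq: str, window: int = TM_WINDOW,
                 threshold: float = TM_THRESHOLD) -> tuple[list[int], np.ndarray]:
    kd = _encode(seq, KYTE_DOOLITTLE)
    wm = _window_means(kd, window)
    covered = np.zeros(len(seq), dtype=bool)
    for i, v in enumerate(wm):
        if v >= threshold:
            covered[i:i + window] = True
    return _runs(covered), wm


def _transmembrane(seq: str) -> np.ndarray:
    runs, wm = _tm_segments(seq)
    n = len(seq)
    covered = sum(runs)
    first = 0.0
    if runs:
        # position of the first covered residue, as a fraction of length
        kd = _encode(seq, KYTE_DOOLITTLE)
        wmask = np.zeros(n, dtype=bool)
        for i, v in enumerate(wm):
            if v >= TM_THRESHOLD:
                wmask[i:i + TM_WINDOW] = True
        first = float(np.argmax(wmask)) / n
    return np.array([
        float(len(runs)),
        covered / n,
        float(wm.max()) if wm.size else float(np.mean(_encode(seq, KYTE_DOOLITTLE))),
        float(wm.mean()) if wm.size else float(np.mean(_encode(seq, KYTE_DOOLITTLE))),
        first,
    ])


def _disorder(seq: str) -> np.ndarray:
    """Windowed TOP-IDP propensity; a residue is disordered when the mean
    propensity of its window exceeds zero."""
    x = _encode(seq, TOP_IDP)
    wm = _window_means(x, DISORDER_WINDOW)
    if wm.size == 0:
        wm = np.array([float(np.mean(x))])
    dis = wm > 0.0
    m = len(dis)
    runs = _runs(dis)
    n = len(seq)
    nterm = dis[: max(1, min(30, m))]
    cterm = dis[-max(1, min(30, m)):]
    return np.array([
        float(dis.sum()) / m,                      # disorder fraction
        (max(runs) / n) if runs else 0.0,          # longest run / length
        float(nterm.mean()),
        float(cterm.mean()),
        len(runs) / n * 100,
        float(np.mean(x)),
    ])


def _signal_peptide(seq: str) -> np.ndarray:
    """N-terminal heuristic: charged n-region followed by a hydrophobic
    h-region within the first ~25 residues."""
    kd = _encode(seq, KYTE_DOOLITTLE)
    head = kd[:25]
    w = 8
    h_scores = _window_means(head, w)
    max_h = float(h_scores.max()) if h_scores.size else float(head.mean())
    n_charge = sum(1 for aa in seq[:5] if aa in POSITIVE)
    indicator = 1.0 if (max_h >= 2.0 and n_charge >= 1) else 0.0
    return np.array([indicator, float(kd[:20].mean()), max_h])


def _low_complexity(seq: str) -> np.ndarray:
    n = len(seq)
    w = LOWCOMP_WINDOW
    ent = []
    for i in range(max(1, n - w + 1)):
        window = seq[i:i + w]
        counts = np.bincount(
            np.fromiter((_AA_INDEX[a] for a in window), dtype=np.intp),
            minlength=20,
        )
        p = counts[counts > 0] / len(window)
        ent.append(float(-(p * np.log2(p)).sum()))
    ent = np.array(ent)
    low = ent < LOWCOMP_ENTROPY
    runs = _runs(low)
    counts = np.bincount(
        np.fromiter((_AA_INDEX[a] for a in seq), dtype=np.intp), minlength=20
    )
    p = counts[counts > 0] / n
    seq_entropy = float(-(p * np.log2(p)).sum())
    return np.array([
        float(low.mean()),
        (max(runs) / n) if runs else 0.0,
        seq_entropy,
    ])


_NGLYC = re.compile(r"N[^P][ST]")
_PKC = re.compile(r"[ST].[RK]")
_CK2 = re.compile(r"[ST]..[DE]")
_TYR = re.compile(r"[RK].{2,3}[DE].{2,3}Y")


def _count_overlapping(pattern: re.Pattern, seq: str) -> int:
    count, pos = 0, 0
    while True:
        m = pattern.search(seq, pos)
        if not m:
            return count
        count += 1
        pos = m.start() + 1


def _glycosylation(seq: str) -> np.ndarray:
    c = _count_overlapping(_NGLYC, seq)
    return np.array([float(c), c / len(seq) * 100])


def _phosphorylation(seq: str) -> np.ndarray:
    n = len(seq)
    pkc = _count_overlapping(_PKC, seq)
    ck2 = _count_overlapping(_CK2, seq)
    tyr = _count_overlapping(_TYR, seq)
    return np.array([
        pkc / n * 100,
        ck2 / n * 100,
        tyr / n * 100,
        (pkc + ck2 + tyr) / n * 100,
    ])


def _coiled_coil(seq: str) -> np.ndarray:
    """Heptad periodicity: for each 28-residue window and each of 7 phases,
    mean hydrophobicity at the a/d core positions minus the rest."""
    kd = _encode(seq, KYTE_DOOLITTLE)
    n = len(seq)
    w = CC_WINDOW
    scores = []
    if n >= w:
        for i in range(n - w + 1):
            win = kd[i:i + w]
            best = -np.inf
            for phase in range(7):
                pos = np.arange(w)
                core = ((pos - phase) % 7 == 0) | ((pos - phase) % 7 == 3)
                best = max(best, float(win[core].mean() - win[~core].mean()))
            scores.append(best)
    if not scores:
        scores = [0.0]
    scores = np.array(scores)
    return np.array([
        float(scores.mean()),
        float(scores.max()),
        float((scores > 1.5).mean()),
    ])


def _hydrophobic_moment(seq: str) -> np.ndarray:
    """Eisenberg hydrophobic moment over 11-residue windows at the
    alpha-helical (100 deg) and beta-strand (160 deg) periodicities."""
    kd = _encode(seq, KYTE_DOOLITTLE)
    out = []
    for angle in (100.0, 160.0):
        rad = math.radians(angle)
        n = len(kd)
        w = HM_WINDOW
        moments = []
        if n >= w:
            k = np.arange(w)
            cos, sin = np.cos(rad * k), np.sin(rad * k)
            for i in range(n - w + 1):
                win = kd[i:i + w]
                mu = math.hypot(float(win @ cos), float(win @ sin)) / w
                moments.append(mu)
        else:
            moments = [0.0]
        moments = np.array(moments)
        out.extend([float(moments.mean()), float(moments.max())])
    return np.array(out)


def _charge_distribution(seq: str) -> np.ndarray:
    n = len(seq)
    pos = np.fromiter((a in POSITIVE for a in seq), dtype=bool, count=n)
    neg = np.fromiter((a in NEGATIVE for a in seq), dtype=bool, count=n)
    fpos, fneg = float(pos.mean()), float(neg.mean())
    fcr = fpos + fneg
    ncpr = fpos - fneg
    half = n // 2
    ncpr_n = float(pos[:half].mean() - neg[:half].mean()) if half else 0.0
    ncpr_c = float(pos[half:].mean() - neg[half:].mean())
    charged_runs = _runs(pos | neg)
    return np.array([
        fpos, fneg, fcr, ncpr,
        abs(ncpr_n - ncpr_c),
        (max(charged_runs) / n) if charged_runs else 0.0,
    ])


_AC_SCALES = (
    KYTE_DOOLITTLE, TOP_IDP, CF_HELIX, CF_SHEET,
    BULKINESS, POLARITY, FLEXIBILITY, CHARGE,
)
_AC_LAGS = 17


def _autocorrelation(seq: str) -> np.ndarray:
    """Moreau-Broto autocorrelation of 8 residue-property scales at lags
    1..17, each scale standardised over the 20 residues."""
    out = np.zeros(len(_AC_SCALES) * _AC_LAGS)
    n = len(seq)
    j = 0
    for scale in _AC_SCALES:
        arr = _scale_array(scale)
        arr = (arr - arr.mean()) / arr.std()
        x = arr[[_AA_INDEX[a] for a in seq]]
        for lag in range(1, _AC_LAGS + 1):
            if n > lag:
                out[j] = float(np.mean(x[:-lag] * x[lag:]))
            j += 1
    return out


# --- registry ---------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One feature group: a name, its scalar count and its extractor."""

    name: str
    size: int
    extractor: Callable[[str], np.ndarray]
    #: externally supplied values, keyed by sequence id (overrides extractor)
    table: Mapping[str, Sequence[float]] | None = None
    #: composition-type groups must sum to one
    composition: bool = False


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered collection of feature groups; the layout contract for vectors."""

    groups: tuple[GroupSpec, ...]

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate feature group names")

    @property
    def total_dim(self) -> int:
        return sum(g.size for g in self.groups)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    def group(self, name: str) -> GroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise LookupError_(f"unknown feature group: {name}")

    def column_names(self) -> list[str]:
        return [f"{g.name}.{i}" for g in self.groups for i in range(g.size)]


def default_registry() -> FeatureRegistry:
    """The standard 14-group, 258-scalar encoding."""
    return FeatureRegistry(groups=(
        GroupSpec("composition", 20, _composition, composition=True),
        GroupSpec("class_pair_composition", 49, _class_pair_composition,
                  composition=True),
        GroupSpec("global_properties", 9, _global_properties),
        GroupSpec("secondary_structure", 8, _secondary_structure),
        GroupSpec("transmembrane", 5, _transmembrane),
        GroupSpec("disorder", 6, _disorder),
        GroupSpec("signal_peptide", 3, _signal_peptide),
        GroupSpec("low_complexity", 3, _low_complexity),
        GroupSpec("glycosylation", 2, _glycosylation),
        GroupSpec("phosphorylation", 4, _phosphorylation),
        GroupSpec("coiled_coil", 3, _coiled_coil),
        GroupSpec("hydrophobic_moment", 4, _hydrophobic_moment),
        GroupSpec("charge_distribution", 6, _charge_distribution),
        GroupSpec("autocorrelation", len(_AC_SCALES) * _AC_LAGS,
                  _autocorrelation),
    ))


@dataclass
class FeatureVector:
    """Feature values for one sequence, organised by group."""

    sequence_id: str
    values: dict[str, np.ndarray]

    def to_array(self, group_names: Sequence[str]) -> np.ndarray:
        parts = []
        for name in group_names:
            if name not in self.values:
                raise LookupError_(
                    f"feature vector {self.sequence_id} lacks group {name}"
                )
            parts.append(self.values[name])
        return np.concatenate(parts) if parts else np.empty(0)

    @property
    def dim(self) -> int:
        return sum(len(v) for v in self.values.values())


def validate_sequence(seq: str) -> None:
    for i, aa in enumerate(seq):
        if aa not in _AA_INDEX:
            raise ValidationError(
                f"nonstandard residue {aa!r} at position {i + 1}"
            )
    if len(seq) < MIN_LENGTH:
        raise ValidationError(
            f"sequence length {len(seq)} below minimum {MIN_LENGTH}"
        )


def extract_features(
    seq: str,
    registry: FeatureRegistry | None = None,
    sequence_id: str = "",
    groups: set[str] | None = None,
) -> FeatureVector:
    """Encode a sequence as a :class:`FeatureVector` under *registry*.

    *groups* restricts extraction to the named groups (all by default).
    Raises :class:`ValidationError` for nonstandard residues (naming the
    position) or sequences shorter than 15 residues.
    """
    registry = registry or default_registry()
    seq = seq.upper()
    validate_sequence(seq)
    values: dict[str, np.ndarray] = {}
    for g in registry.groups:
        if groups is not None and g.name not in groups:
            continue
        if g.table is not None:
            if sequence_id not in g.table:
                raise LookupError_(
                    f"external group {g.name}: no values for {sequence_id!r}"
                )
            v = np.asarray(g.table[sequence_id], dtype=float)
        else:
            v = np.asarray(g.extractor(seq), dtype=float)
        if len(v) != g.size:
            raise ValidationError(
                f"group {g.name}: extractor returned {len(v)} values, "
                f"expected {g.size}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"group {g.name}: non-finite feature value")
        values[g.name] = v
    return FeatureVector(sequence_id=sequence_id, values=values)


def register_external_group(
    registry: FeatureRegistry,
    name: str,
    values_by_protein: Mapping[str, Sequence[float]],
) -> FeatureRegistry:
    """Replace a group's extractor with a lookup table of external values.

    The replacement keeps the group's declared scalar count; extraction then
    fails with a lookup error for any sequence id missing from the table.
    """
    target = registry.group(name)
    for k, v in values_by_protein.items():
        if len(v) != target.size:
            raise ValidationError(
                f"external values for {k!r} have length {len(v)}, "
                f"expected {target.size}"
            )
    new_groups = tuple(
        replace(g, table=dict(values_by_protein)) if g.name == name else g
        for g in registry.groups
    )
    return FeatureRegistry(groups=new_groups)


def mask_groups(vec: FeatureVector, keep: set[str],
                registry: FeatureRegistry | None = None) -> FeatureVector:
    """Keep only the named groups; the basis of backward group elimination."""
    registry = registry or default_registry()
    known = set(registry.group_names)
    unknown = set(keep) - known
    if unknown:
        raise LookupError_(f"unknown feature groups: {sorted(unknown)}")
    values = {k: v for k, v in vec.values.items() if k in keep}
    return FeatureVector(sequence_id=vec.sequence_id, values=values)


def feature_matrix(
    vectors: Sequence[FeatureVector], group_names: Sequence[str]
) -> np.ndarray:
    """Stack vectors into an (n_sequences, n_features) matrix."""
    return np.vstack([v.to_array(group_names) for v in vectors])
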