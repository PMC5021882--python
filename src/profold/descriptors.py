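"""The four descriptor groups used for fold classification.

Every protein is represented by up to four feature views:

* **DSSP** (40D) — statistics of the eight-state secondary-structure string:
  state and group compositions, counts and coverage of continuous (length
  >= 2) runs, and the frequency of group alternation at adjacent positions.
* **AAsCPP** (188D) — amino-acid composition (20D) plus, for each of eight
  physicochemical properties, a composition/transition/distribution (CTD)
  block of 21 values (3 + 3 + 15), giving 20 + 8*21 = 188.
* **PSSM** (20D) — the per-column mean of the L x 20 log-odds profile:
  component j is (1/L) * sum_i S_ij.
* **FunD** (|universe|D, binary) — functional-domain occupancy over a fixed
  ordered domain universe: 1 where some hit to that domain has expect value
  <= 0.001 (inclusive), else 0.

Physicochemical groupings follow the classical three-group partitions of
the 20 standard amino acids (hydrophobicity, van der Waals volume, polarity,
polarizability, charge, surface tension, secondary-structure propensity,
solvent accessibility). Nonstandard residue letters (B, J, O, U, X, Z) are
dropped before any sequence-composition statistic is computed; both
numerators and denominators count standard residues only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .formats_io import (
    DSSP_STATES,
    DomainHitTable,
    DsspString,
    FeatureGroupMatrix,
    PssmMatrix,
)

__all__ = [
    "AMINO_ACIDS",
    "GROUPING_SCHEMES",
    "PROPERTY_ORDER",
    "DSSP_GROUP_MAP",
    "GroupingScheme",
    "DomainUniverse",
    "FeatureVector",
    "dssp_state_composition",
    "dssp_group_composition",
    "dssp_run_counts",
    "dssp_group_run_counts",
    "dssp_run_compositions",
    "dssp_group_run_compositions",
    "dssp_group_alternation",
    "extract_dssp_features",
    "aa_composition",
    "ctd_composition",
    "ctd_transition",
    "ctd_distribution",
    "extract_aascpp_features",
    "extract_pssm_features",
    "extract_fund_features",
    "dssp_feature_names",
    "aascpp_feature_names",
    "pssm_feature_names",
]

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Secondary-structure state -> structural group (1 helix, 2 strand,
#: 3 turn/bend, 4 irregular).
DSSP_GROUP_MAP: dict[str, int] = {
    "G": 1, "H": 1, "I": 1,
    "E": 2, "B": 2,
    "T": 3, "S": 3,
    "L": 4,
}


@dataclass(frozen=True)
class GroupingScheme:
    """A three-group partition of the 20 standard amino acids."""

    property_name: str
    groups: tuple[str, str, str]

    def __post_init__(self) -> None:
        pooled = "".join(self.groups)
        if sorted(pooled) != sorted(AMINO_ACIDS):
            raise ValueError(
                f"{self.property_name}: groups {self.groups} are not a "
                "partition of the 20 standard amino acids"
            )

    def group_of(self, residue: str) -> int:
        """1-based group index of a standard residue."""
        for g, members in enumerate(self.groups, start=1):
            if residue in members:
                return g
        raise KeyError(residue)

    def lookup(self) -> dict[str, int]:
        return {aa: g for g, members in enumerate(self.groups, start=1) for aa in members}


#: Property order used when concatenating per-property CTD blocks.
PROPERTY_ORDER = (
    "hydrophobicity",
    "van_der_waals_volume",
    "polarity",
    "polarizability",
    "charge",
    "surface_tension",
    "secondary_structure",
    "solvent_accessibility",
)

# Three-group amino-acid partitions per physicochemical property.
# The polarity low-polarity group is LIFWCMVY (the classical partition);
# sources occasionally misprint the Y of this group as a duplicate F.
GROUPING_SCHEMES: dict[str, GroupingScheme] = {
    "hydrophobicity": GroupingScheme(
        "hydrophobicity", ("RKEDQN", "GASTPHY", "CVLIMFW")
    ),
    "van_der_waals_volume": GroupingScheme(
        "van_der_waals_volume", ("GASCTPD", "NVEQIL", "MHKFRYW")
    ),
    "polarity": GroupingScheme(
        "polarity", ("LIFWCMVY", "PATGS", "HQRKNED")
    ),
    "polarizability": GroupingScheme(
        "polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")
    ),
    "charge": GroupingScheme(
        "charge", ("KR", "ANCQGHILMFPSTWYV", "DE")
    ),
    "surface_tension": GroupingScheme(
        "surface_tension", ("GQDNAHR", "KTSEC", "ILMFPWYV")
    ),
    "secondary_structure": GroupingScheme(
        "secondary_structure", ("EALMQKRH", "VIYCWFT", "GNPSD")
    ),
    "solvent_accessibility": GroupingScheme(
        "solvent_accessibility", ("ALFCGIVW", "RKQEND", "MPSTHY")
    ),
}


@dataclass(frozen=True)
class DomainUniverse:
    """A fixed, ordered universe of domain identifiers (the FunD bases)."""

    domain_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.domain_ids) == 0:
            raise ValueError("domain universe must be nonempty")
        if len(set(self.domain_ids)) != len(self.domain_ids):
            raise ValueError("domain ids must be unique")

    @property
    def size(self) -> int:
        return len(self.domain_ids)

    def index_of(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.domain_ids)}


@dataclass(frozen=True)
class FeatureVector:
    """One sample's descriptor values for one feature group."""

    group_name: str
    values: np.ndarray
    column_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.column_names):
            raise ValueError("values and column_names must have equal length")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# DSSP descriptor blocks
# ---------------------------------------------------------------------------

def _dssp_groups(s: DsspString) -> list[int]:
    return [DSSP_GROUP_MAP[c] for c in s.states]


def _runs(symbols, min_len: int = 2):
    """Maximal runs of identical symbols with length >= min_len.

    Yields (symbol, run_length).
    """
    i, n = 0, len(symbols)
    while i < n:
        j = i
        while j < n and symbols[j] == symbols[i]:
            j += 1
        if j - i >= min_len:
            yield symbols[i], j - i
        i = j


def dssp_state_composition(s: DsspString) -> np.ndarray:
    """Fraction of positions in each of the eight states (order GHIEBTSL)."""
    counts = np.array([s.states.count(c) for c in DSSP_STATES], dtype=float)
    return counts / len(s)


def dssp_group_composition(s: DsspString) -> np.ndarray:
    """Fraction of positions in each of the four structural groups."""
    groups = _dssp_groups(s)
    counts = np.array([groups.count(g) for g in (1, 2, 3, 4)], dtype=float)
    return counts / len(s)


def dssp_run_counts(s: DsspString) -> np.ndarray:
    """Per state, the number of maximal runs of length >= 2."""
    counts = dict.fromkeys(DSSP_STATES, 0)
    for sym, _ in _runs(s.states):
        counts[sym] += 1
    return np.array([counts[c] for c in DSSP_STATES], dtype=float)


def dssp_group_run_counts(s: DsspString) -> np.ndarray:
    """Per structural group, the number of maximal runs of length >= 2."""
    counts = {g: 0 for g in (1, 2, 3, 4)}
    for sym, _ in _runs(_dssp_groups(s)):
        counts[sym] += 1
    return np.array([counts[g] for g in (1, 2, 3, 4)], dtype=float)


def dssp_run_compositions(s: DsspString) -> np.ndarray:
    """Per state, the fraction of positions inside length >= 2 runs."""
    covered = dict.fromkeys(DSSP_STATES, 0)
    for sym, length in _runs(s.states):
        covered[sym] += length
    return np.array([covered[c] for c in DSSP_STATES], dtype=float) / len(s)


def dssp_group_run_compositions(s: DsspString) -> np.ndarray:
    """Per structural group, the fraction of positions inside length >= 2 runs."""
    covered = {g: 0 for g in (1, 2, 3, 4)}
    for sym, length in _runs(_dssp_groups(s)):
        covered[sym] += length
    return np.array([covered[g] for g in (1, 2, 3, 4)], dtype=float) / len(s)


def dssp_group_alternation(s: DsspString) -> np.ndarray:
    """Per group, the frequency of group changes at adjacent positions.

    For group g: the number of adjacent pairs (i, i+1) whose groups differ
    and where one endpoint belongs to g, divided by L - 1. All zeros for a
    length-1 string.
    """
    groups = _dssp_groups(s)
    if len(groups) < 2:
        return np.zeros(4)
    counts = {g: 0 for g in (1, 2, 3, 4)}
    for a, b in zip(groups, groups[1:]):
        if a != b:
            counts[a] += 1
            counts[b] += 1
    denom = len(groups) - 1
    return np.array([counts[g] for g in (1, 2, 3, 4)], dtype=float) / denom


def dssp_feature_names() -> tuple[str, ...]:
    names: list[str] = []
    names += [f"dssp.comp.{c}" for c in DSSP_STATES]
    names += [f"dssp.groupcomp.g{g}" for g in (1, 2, 3, 4)]
    names += [f"dssp.runs.{c}" for c in DSSP_STATES]
    names += [f"dssp.groupruns.g{g}" for g in (1, 2, 3, 4)]
    names += [f"dssp.runcomp.{c}" for c in DSSP_STATES]
    names += [f"dssp.grouprun.comp.g{g}" for g in (1, 2, 3, 4)]
    names += [f"dssp.alt.g{g}" for g in (1, 2, 3, 4)]
    return tuple(names)


def extract_dssp_features(s: DsspString) -> FeatureVector:
    """The 40D secondary-structure descriptor.

    Blocks, in order: state composition (8), group composition (4), state
    run counts (8), group run counts (4), state run coverage (8), group run
    coverage (4), group alternation (4).
    """
    values = np.concatenate([
        dssp_state_composition(s),
        dssp_group_composition(s),
        dssp_run_counts(s),
        dssp_group_run_counts(s),
        dssp_run_compositions(s),
        dssp_group_run_compositions(s),
        dssp_group_alternation(s),
    ])
    return FeatureVector("DSSP", values, dssp_feature_names())


# ---------------------------------------------------------------------------
# AAsCPP: amino-acid composition + CTD blocks
# ---------------------------------------------------------------------------

def _standard_only(seq: str) -> str:
    seq = seq.upper()
    return "".join(c for c in seq if c in AMINO_ACIDS)


def aa_composition(seq: str) -> np.ndarray:
    """Fraction of each standard amino acid (alphabetical order).

    Nonstandard letters are excluded from numerator and denominator. Raises
    ValueError if the sequence contains no standard residue.
    """
    std = _standard_only(seq)
    if not std:
        raise ValueError("sequence contains no standard amino acid")
    counts = np.array([std.count(a) for a in AMINO_ACIDS], dtype=float)
    return counts / len(std)


def ctd_composition(seq: str, scheme: GroupingScheme) -> np.ndarray:
    """Fraction of standard residues in each of the scheme's three groups."""
    std = _standard_only(seq)
    if not std:
        raise ValueError("sequence contains no standard amino acid")
    lut = scheme.lookup()
    groups = [lut[c] for c in std]
    counts = np.array([groups.count(g) for g in (1, 2, 3)], dtype=float)
    return counts / len(std)


#: Unordered group-pair order for transition features.
_PAIR_ORDER = ((1, 2), (1, 3), (2, 3))


def ctd_transition(seq: str, scheme: GroupingScheme) -> np.ndarray:
    """Frequency of adjacent residue pairs spanning two different groups.

    Component order: pairs (1,2), (1,3), (2,3), either orientation; each
    count divided by L' - 1 where L' is the standard-residue count. All
    zeros for L' = 1.
    """
    std = _standard_only(seq)
    if not std:
        raise ValueError("sequence contains no standard amino acid")
    if len(std) == 1:
        return np.zeros(3)
    lut = scheme.lookup()
    groups = [lut[c] for c in std]
    counts = {p: 0 for p in _PAIR_ORDER}
    for a, b in zip(groups, groups[1:]):
        if a != b:
            counts[(min(a, b), max(a, b))] += 1
    return np.array([counts[p] for p in _PAIR_ORDER], dtype=float) / (len(std) - 1)


def ctd_distribution(seq: str, scheme: GroupingScheme) -> np.ndarray:
    """Normalized positions of the first/25%/50%/75%/100% group occurrences.

    For each group g with n_g occurrences in the standard-residue-only
    sequence of length L': the 1-based positions of the 1st occurrence and
    of occurrence number ceil(q * n_g) for q in {0.25, 0.5, 0.75, 1.0},
    each divided by L'. A group with no occurrence contributes five zeros.
    Returns 15 values (3 groups x 5 quantiles).
    """
    std = _standard_only(seq)
    if not std:
        raise ValueError("sequence contains no standard amino acid")
    lut = scheme.lookup()
    groups = [lut[c] for c in std]
    L = len(std)
    out: list[float] = []
    for g in (1, 2, 3):
        positions = [i + 1 for i, gg in enumerate(groups) if gg == g]
        if not positions:
            out.extend([0.0] * 5)
            continue
        n_g = len(positions)
        out.append(positions[0] / L)
        for q in (0.25, 0.5, 0.75, 1.0):
            idx = max(1, math.ceil(q * n_g))
            out.append(positions[idx - 1] / L)
    return np.array(out)


def aascpp_feature_names() -> tuple[str, ...]:
    names = [f"aascpp.aac.{a}" for a in AMINO_ACIDS]
    quantiles = ("p0", "p25", "p50", "p75", "p100")
    for prop in PROPERTY_ORDER:
        names += [f"aascpp.{prop}.C.g{g}" for g in (1, 2, 3)]
        names += [f"aascpp.{prop}.T.g{a}g{b}" for a, b in _PAIR_ORDER]
        for g in (1, 2, 3):
            names += [f"aascpp.{prop}.D.g{g}.{q}" for q in quantiles]
    return tuple(names)


def extract_aascpp_features(seq: str) -> FeatureVector:
    """The 188D composition + physicochemical descriptor.

    20D amino-acid composition followed by a 21D CTD block (composition 3,
    transition 3, distribution 15) for each of the eight properties.
    """
    blocks = [aa_composition(seq)]
    for prop in PROPERTY_ORDER:
        scheme = GROUPING_SCHEMES[prop]
        blocks.append(ctd_composition(seq, scheme))
        blocks.append(ctd_transition(seq, scheme))
        blocks.append(ctd_distribution(seq, scheme))
    return FeatureVector("AAsCPP", np.concatenate(blocks), aascpp_feature_names())


# ---------------------------------------------------------------------------
# PSSM column means
# ---------------------------------------------------------------------------

def pssm_feature_names(column_order=None) -> tuple[str, ...]:
    from .formats_io import PSSM_COLUMNS

    cols = tuple(column_order) if column_order is not None else PSSM_COLUMNS
    return tuple(f"pssm.mean.{c}" for c in cols)


def extract_pssm_features(m: PssmMatrix) -> FeatureVector:
    """The 20D column-mean of the log-odds profile: (1/L) * sum_i S_ij."""
    values = m.scores.mean(axis=0)
    return FeatureVector("PSSM", values, pssm_feature_names(m.column_order))


# ---------------------------------------------------------------------------
# Functional-domain occupancy
# ---------------------------------------------------------------------------

def extract_fund_features(
    hits: DomainHitTable,
    universe: DomainUniverse,
    threshold: float = 0.001,
) -> FeatureVector:
    """Binary domain-occupancy vector over a fixed domain universe.

    A component is 1 iff some hit to that domain has E-value <= threshold
    (the comparison is inclusive). Hits to domains outside the universe are
    ignored with a warning.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be nonnegative, got {threshold}")
    index = universe.index_of()
    values = np.zeros(universe.size)
    for domain_id, e_value in hits.hits:
        if domain_id not in index:
            logger.warning("domain hit %s outside the universe; ignored", domain_id)
            continue
        if e_value <= threshold:
            values[index[domain_id]] = 1.0
    names = tuple(f"fund.{d}" for d in universe.domain_ids)
    return FeatureVector("FunD", values, names)


# ---------------------------------------------------------------------------
# Batch helpers: many samples -> one FeatureGroupMatrix
# ---------------------------------------------------------------------------

def stack_feature_vectors(
    group_name: str, sample_ids: list[str], vectors: list[FeatureVector]
) -> FeatureGroupMatrix:
    """Assemble per-sample vectors (identical column sets) into a matrix."""
    if len(sample_ids) != len(vectors):
        raise ValueError("one feature vector per sample id required")
    if not vectors:
        raise ValueError("at least one sample required")
    columns = vectors[0].column_names
    for sid, v in zip(sample_ids, vectors):
        if v.column_names != columns:
            raise ValueError(f"sample {sid}: column names differ from first sample")
    return FeatureGroupMatrix(
        group_name=group_name,
        sample_ids=list(sample_ids),
        values=np.vstack([v.values for v in vectors]),
        column_names=list(columns),
    )
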