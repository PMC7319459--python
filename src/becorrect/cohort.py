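"""Batch analysis of pathogenic SNV cohorts.

Filters a raw variant table down to usable single-nucleotide substitutions
(indels, multi-nucleotide variants and mitochondrial records are excluded —
the mitochondrial genetic code differs from the standard one), runs the
correction search per record, and aggregates repairability statistics:
fractions of repairable transitions, the share fixable only through
synonymous corrections, repairable transversions, and a per-amino-acid
substitution recovery matrix for transversion-derived mutations.

Cohort repairability counts MAJOR-window corrections only: the feasibility
question is about efficient editing, and minor windows edit at much lower
rates. Minor-only matches are tallied separately.
"""

from __future__ import annotations

import io
import itertools
import json
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .classify import find_corrections
from .editors import EditorRegistry
from .placement import SnvRecord
from .seqcore import SequenceError, is_transition

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "CohortSummary",
    "apply_exclusion_filters",
    "summarize",
    "recoverable_substitution_table",
]

#: Default mapping from logical fields to input-table column names. The
#: supplementary tables in circulation vary, so callers can override any entry.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "id": "id",
    "chrom": "chrom",
    "ref": "ref_base",
    "var": "var_base",
    "sequence": "sequence",
    "position": "snv_pos",
    "frame": "frame_offset",
}

_MITO_NAMES = {"CHRM", "CHRMT", "MT", "M"}

_CODON_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_AA[_stop] = "*"
_SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))

_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_CHEMISTRIES = ("C>T", "A>G", "G>A", "T>C")  # incl. the minus-strand views


@dataclass
class CohortSummary:
    n_total: int = 0
    n_transitions: int = 0
    n_transversions: int = 0
    n_transitions_repairable: int = 0
    n_transitions_synonymous_only: int = 0
    n_transversions_repairable: int = 0
    n_minor_only: int = 0  # records matched only through minor windows
    aa_substitution_matrix: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def pct_transitions_repairable(self) -> float:
        return 100.0 * self.n_transitions_repairable / self.n_transitions if self.n_transitions else 0.0

    @property
    def pct_synonymous_only(self) -> float:
        """Share of repairable transitions fixable only synonymously."""
        if not self.n_transitions_repairable:
            return 0.0
        return 100.0 * self.n_transitions_synonymous_only / self.n_transitions_repairable

    @property
    def pct_transversions_repairable(self) -> float:
        return (
            100.0 * self.n_transversions_repairable / self.n_transversions
            if self.n_transversions
            else 0.0
        )

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_transitions": self.n_transitions,
            "n_transversions": self.n_transversions,
            "n_transitions_repairable": self.n_transitions_repairable,
            "n_transitions_synonymous_only": self.n_transitions_synonymous_only,
            "n_transversions_repairable": self.n_transversions_repairable,
            "n_minor_only": self.n_minor_only,
            "pct_transitions_repairable": round(self.pct_transitions_repairable, 1),
            "pct_synonymous_only": round(self.pct_synonymous_only, 1),
            "pct_transversions_repairable": round(self.pct_transversions_repairable, 1),
            "aa_substitution_matrix": {
                f"{r}>{v}": list(cell) for (r, v), cell in sorted(self.aa_substitution_matrix.items())
            },
            "excluded": dict(sorted(self.excluded.items())),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def matrix_to_tsv(self) -> str:
        """Per-substitution recovery table (reference AA x variant AA)."""
        buf = io.StringIO()
        buf.write("ref_aa\tvar_aa\tn_occurrences\tn_repairable\n")
        for (r, v), (n_occ, n_rep) in sorted(self.aa_substitution_matrix.items()):
            buf.write(f"{r}\t{v}\t{n_occ}\t{n_rep}\n")
        return buf.getvalue()


def apply_exclusion_filters(
    records: pd.DataFrame, column_map: dict[str, str] | None = None
) -> tuple[list[SnvRecord], dict[str, int]]:
    """Filter a raw variant table to usable SNV records.

    Keeps single-nucleotide substitutions on non-mitochondrial chromosomes
    with a usable sequence, position and frame; returns the retained records
    and exclusion counts keyed by reason (indel_or_mnv / mitochondrial /
    invalid).
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    required = ["id", "ref", "var", "sequence", "position", "frame"]
    missing = [colmap[k] for k in required if colmap[k] not in records.columns]
    if missing:
        raise KeyError(f"variant table is missing required columns: {missing}")
    has_chrom = colmap["chrom"] in records.columns
    kept: list[SnvRecord] = []
    excluded: Counter[str] = Counter()
    for _, row in records.iterrows():
        ref = str(row[colmap["ref"]]).strip().upper()
        var = str(row[colmap["var"]]).strip().upper()
        if len(ref) != 1 or len(var) != 1 or ref == "-" or var == "-":
            excluded["indel_or_mnv"] += 1
            continue
        if has_chrom and str(row[colmap["chrom"]]).strip().upper() in _MITO_NAMES:
            excluded["mitochondrial"] += 1
            continue
        try:
            kept.append(
                SnvRecord(
                    id=str(row[colmap["id"]]),
                    sequence=str(row[colmap["sequence"]]),
                    snv_pos=int(row[colmap["position"]]),
                    ref_base=ref,
                    var_base=var,
                    frame_offset=int(row[colmap["frame"]]),
                )
            )
        except (SequenceError, ValueError, TypeError):
            excluded["invalid"] += 1
    return kept, dict(excluded)


def _snv_codon_pair(snv: SnvRecord) -> tuple[str, str] | None:
    """(reference AA, variant AA) of the codon holding the SNV, or None if the
    SNV falls outside a complete codon."""
    i = snv.snv_pos - 1
    if i < snv.frame_offset:
        return None
    codon_start = snv.frame_offset + 3 * ((i - snv.frame_offset) // 3)
    if codon_start + 3 > len(snv.sequence):
        return None
    var_codon = snv.sequence[codon_start : codon_start + 3]
    offset = i - codon_start
    ref_codon = var_codon[:offset] + snv.ref_base + var_codon[offset + 1 :]
    return _CODON_AA[ref_codon], _CODON_AA[var_codon]


def summarize(records: list[SnvRecord], registry: EditorRegistry) -> CohortSummary:
    """Run the correction search over a cohort and aggregate repair statistics.

    A record is repairable when at least one major-window correction exists;
    it is synonymous-only when repairable with no precise correction. The
    amino-acid substitution matrix covers transversion records (the rescue
    classes of interest — transitions are trivially matched at the DNA level).
    """
    summary = CohortSummary(n_total=len(records))
    matrix: dict[tuple[str, str], list[int]] = {}
    for snv in records:
        transition = is_transition(snv.ref_base, snv.var_base)
        if transition:
            summary.n_transitions += 1
        else:
            summary.n_transversions += 1
        results = find_corrections(snv, registry, include_minor=True)
        major = [r for r in results if not r.outcome.minor_window_match]
        repairable = bool(major)
        if results and not major:
            summary.n_minor_only += 1
        if transition:
            if repairable:
                summary.n_transitions_repairable += 1
                if not any(r.is_precise for r in major):
                    summary.n_transitions_synonymous_only += 1
        else:
            if repairable:
                summary.n_transversions_repairable += 1
            pair = _snv_codon_pair(snv)
            if pair is not None:
                cell = matrix.setdefault(pair, [0, 0])
                cell[0] += 1
                if repairable:
                    cell[1] += 1
    summary.aa_substitution_matrix = {k: (v[0], v[1]) for k, v in matrix.items()}
    return summary


def _apply_chemistry(codon: str, chem: str, positions: tuple[int, ...]) -> str:
    src, dst = chem[0], chem[2]
    return "".join(
        dst if (i in positions and b == src) else b for i, b in enumerate(codon)
    )


@lru_cache(maxsize=1)
def recoverable_substitution_table() -> dict[tuple[str, str], bool]:
    """Codon-level (PAM-free) recoverability of transversion-derived
    amino-acid substitutions.

    For every sense codon and every single-base transversion of it, tests
    whether some single-chemistry transition edit — all source bases within
    one contiguous codon interval convert at once — restores the reference
    amino acid. This is the theoretical upper bound on what placement search
    can find: PAM and window constraints can only shrink the recoverable set.
    Keys are (reference AA, variant AA) for non-silent substitutions; a pair
    is True when at least one codon context admits a rescue.
    """
    intervals = [tuple(range(a, b + 1)) for a in range(3) for b in range(a, 3)]
    table: dict[tuple[str, str], bool] = {}
    for ref_codon in _SENSE_CODONS:
        ref_aa = _CODON_AA[ref_codon]
        for pos, alt in itertools.product(range(3), "ACGT"):
            if alt not in _TRANSVERSIONS[ref_codon[pos]]:
                continue
            var_codon = ref_codon[:pos] + alt + ref_codon[pos + 1 :]
            var_aa = _CODON_AA[var_codon]
            if var_aa == ref_aa:
                continue  # silent variant, not a pathogenic substitution
            key = (ref_aa, var_aa)
            recoverable = table.get(key, False)
            if not recoverable:
                for chem, interval in itertools.product(_CHEMISTRIES, intervals):
                    edited = _apply_chemistry(var_codon, chem, interval)
                    if edited != var_codon and _CODON_AA[edited] == ref_aa:
                        recoverable = True
                        break
            table[key] = recoverable
    return table
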