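"""Synthetic SNV fixtures with known ground truth.

Each generated record is a random coding sequence into which one mutation of
a requested correction class is implanted together with (or deliberately
without) a PAM that puts the SNV in a suitable editor's activity window:

* precise — a transition SNV that is the only source base in the planted
  editor's major window, so the deterministic edit restores the reference DNA
  exactly;
* multiple_bases_synonymous — the classic ACTCTA->ATTTTA situation: the SNV
  and one bystander cytosine share the window, and the bystander edit is
  silent;
* on_target_synonymous — an AGG->TGG (Arg->Trp) transversion whose variant T
  is converted to C by a minus-strand adenine editor, yielding the synonymous
  CGG;
* bystander_synonymous — a TTA->TTT (Leu->Phe) transversion: codon position 1
  sits in the major window (T->C gives the synonymous CTT) while the SNV
  itself is reachable only through a minor window, so the match carries the
  minor-window flag;
* unrepairable — a GCC->GAC (Ala->Asp) transversion, a substitution that no
  single-chemistry transition edit set can revert at the codon level, hence
  unrepairable regardless of any PAM context.

Ground truth is "the planted correction exists": incidental extra
corrections arising from the random flanks are allowed and tolerated.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table

from .editors import FIVE_PRIME, EditorRegistry, builtin_registry
from .placement import SnvRecord
from .seqcore import IUPAC_CODES

__all__ = ["FixtureSpec", "FixtureError", "generate_fixture", "random_snv_record"]

_SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))

#: Default class proportions for mixed cohorts: transitions dominate real
#: pathogenic SNV collections and most feasible corrections are precise, so
#: precise carries the largest share, with a sizeable unrepairable remainder.
DEFAULT_MIX: dict[str, float] = {
    "precise": 0.35,
    "multiple_bases_synonymous": 0.15,
    "on_target_synonymous": 0.15,
    "bystander_synonymous": 0.10,
    "unrepairable": 0.25,
}

_BE3 = "BE1/BE2/BE3/HF-BE3/BE4(max)/BE4-Gam"


class FixtureError(ValueError):
    """A fixture request cannot be satisfied; the message names the class."""


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_records: int = 20
    cds_length: int = 120
    scenario_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    editor_pool: tuple[str, ...] = (_BE3, "ABE 7.10")

    def __post_init__(self) -> None:
        if self.cds_length < 30 or self.cds_length % 3:
            raise FixtureError(
                f"cds_length must be a multiple of 3 and >= 30, got {self.cds_length}"
            )
        unknown = set(self.scenario_mix) - set(DEFAULT_MIX)
        if unknown:
            raise FixtureError(f"unknown scenario class(es): {sorted(unknown)}")
        total = sum(self.scenario_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise FixtureError(f"scenario_mix proportions must sum to 1, got {total}")
        if self.n_records < 1:
            raise FixtureError("n_records must be positive")


def _random_cds(rng: random.Random, length: int) -> list[str]:
    return list("".join(rng.choice(_SENSE_CODONS) for _ in range(length // 3)))


def _concrete_pam(rng: random.Random, pattern: str) -> str:
    return "".join(rng.choice(sorted(IUPAC_CODES[c])) for c in pattern)


def _non(rng: random.Random, base: str) -> str:
    return rng.choice(sorted(set("ACGT") - {base}))


def _codon_starts(lo: int, hi: int, length: int) -> list[int]:
    """Codon-aligned starts c with lo <= c <= hi and c + 3 <= length."""
    first = ((max(lo, 0) + 2) // 3) * 3
    return [c for c in range(first, min(hi, length - 3) + 1, 3)]


def _plant_precise(rng, seq, registry, editor_name):
    editor = registry.lookup(editor_name)
    if editor.context_rule is not None:
        raise FixtureError(f"precise: cannot plant for context-restricted editor {editor_name}")
    n = len(seq)
    L, P = editor.grna_length, len(editor.pam)
    lo, hi = editor.major_window
    d = (lo + hi) // 2
    if editor.pam_side == FIVE_PRIME:
        # proto_start = i - d + 1; PAM occupies [proto_start - P, proto_start)
        feasible = [i for i in range(n) if i - d + 1 - P >= 0 and i - d + 1 + L <= n]
    else:
        # proto_start = i + d - L; PAM occupies [i + d, i + d + P)
        feasible = [i for i in range(n) if i + d - L >= 0 and i + d + P <= n]
    if not feasible:
        raise FixtureError(f"precise: cds_length {n} too short for editor {editor_name}")
    i = rng.choice(feasible)
    src, product = editor.source_base, editor.product_base
    if editor.pam_side == FIVE_PRIME:
        proto_start = i - d + 1
        window = range(proto_start + lo - 1, proto_start + hi)
        pam_lo = proto_start - P
    else:
        proto_start = i + d - L
        window = range(proto_start + L - hi, proto_start + L - lo + 1)
        pam_lo = proto_start + L
    for idx in window:
        if idx != i:
            seq[idx] = _non(rng, src)
    seq[i] = src
    seq[pam_lo : pam_lo + P] = _concrete_pam(rng, editor.pam)
    return i + 1, product, src, editor.name


def _plant_multiple_bases(rng, seq, registry):
    # BE3 family, plus strand, SNV at distance 16: the major window (13-17)
    # covers the ACTCTA segment's two cytosines and nothing else.
    n = len(seq)
    starts = _codon_starts(3, n - 20 - 1, n - 3)
    if not starts:
        raise FixtureError(f"multiple_bases_synonymous: cds_length {n} too short")
    c0 = rng.choice(starts)
    i = c0 + 1
    seq[c0 : c0 + 6] = list("ACTCTA")
    seq[i + 16 : i + 19] = list(_concrete_pam(rng, "NGG"))
    return i + 1, "T", "C", _BE3


def _plant_on_target(rng, seq, registry):
    # Arg AGG -> Trp TGG transversion; ABE 7.10 on the minus strand converts
    # the variant T (distance 15) to C, giving the synonymous CGG.
    n = len(seq)
    starts = _codon_starts(18, n - 6, n)
    if not starts:
        raise FixtureError(f"on_target_synonymous: cds_length {n} too short")
    i = rng.choice(starts)
    seq[i : i + 3] = list("TGG")
    seq[i - 1] = _non(rng, "T")  # keep the major window free of other targets
    seq[i - 17 : i - 14] = ["C", "C", _non(rng, "C")]  # minus-strand NGG
    return i + 1, "A", "T", "ABE 7.10"


def _plant_bystander(rng, seq, registry):
    # Leu TTA -> Phe TTT transversion; with ABE 7.10* on the minus strand the
    # codon's first T sits at distance 17 (major, edits to C -> CTT, Leu) while
    # the SNV at distance 19 is covered only by the minor window. A contiguous
    # major window reaching the SNV would co-edit codon position 2 and break
    # the protein, so this class is inherently a minor-window match.
    n = len(seq)
    starts = _codon_starts(21, n - 4, n)
    if not starts:
        raise FixtureError(f"bystander_synonymous: cds_length {n} too short")
    j = rng.choice(starts)
    seq[j : j + 3] = list("TTT")
    for idx in range(j - 4, j):
        seq[idx] = _non(rng, "T")
    seq[j - 19 : j - 16] = ["C", "C", _non(rng, "C")]  # minus-strand NGG
    return j + 3, "A", "T", "ABE 7.10*"


def _plant_unrepairable(rng, seq, registry):
    # Ala GCC -> Asp GAC: no single-chemistry transition edit set restores Ala
    # at the codon level, so no placement anywhere can yield a correction.
    n = len(seq)
    starts = _codon_starts(0, n - 3, n)
    c0 = rng.choice(starts)
    seq[c0 : c0 + 3] = list("GAC")
    return c0 + 2, "C", "A", ""


_PLANTERS = {
    "multiple_bases_synonymous": _plant_multiple_bases,
    "on_target_synonymous": _plant_on_target,
    "bystander_synonymous": _plant_bystander,
    "unrepairable": _plant_unrepairable,
}


def _scenario_sequence(spec: FixtureSpec, rng: random.Random) -> list[str]:
    """Deterministic apportionment of n_records over the mix, then shuffled."""
    items = sorted(spec.scenario_mix.items())
    counts = {name: int(spec.n_records * p) for name, p in items}
    remainders = sorted(
        items, key=lambda kv: (spec.n_records * kv[1]) - counts[kv[0]], reverse=True
    )
    short = spec.n_records - sum(counts.values())
    for name, _ in remainders[:short]:
        counts[name] += 1
    scenarios = [name for name, c in sorted(counts.items()) for _ in range(c)]
    rng.shuffle(scenarios)
    return scenarios


def generate_fixture(
    spec: FixtureSpec, registry: EditorRegistry | None = None
) -> tuple[list[SnvRecord], dict[str, str]]:
    """Generate SNV records with planted correction classes.

    Returns the records and a ground-truth map from record id to the planted
    scenario. Generation is fully reproducible from ``spec.seed``.
    """
    registry = registry or builtin_registry()
    rng = random.Random(spec.seed)
    records: list[SnvRecord] = []
    labels: dict[str, str] = {}
    for k, scenario in enumerate(_scenario_sequence(spec, rng)):
        seq = _random_cds(rng, spec.cds_length)
        if scenario == "precise":
            editor_name = rng.choice(list(spec.editor_pool))
            snv_pos, ref, var, _ = _plant_precise(rng, seq, registry, editor_name)
        else:
            snv_pos, ref, var, _ = _PLANTERS[scenario](rng, seq, registry)
        rec_id = f"rec{k:04d}"
        records.append(
            SnvRecord(
                id=rec_id,
                sequence="".join(seq),
                snv_pos=snv_pos,
                ref_base=ref,
                var_base=var,
                frame_offset=0,
            )
        )
        labels[rec_id] = scenario
    return records, labels


def random_snv_record(rng: random.Random, length: int = 60, rec_id: str = "rand") -> SnvRecord:
    """A uniformly random SNV record, for property tests against brute force."""
    seq = "".join(rng.choice("ACGT") for _ in range(length))
    pos = rng.randrange(length) + 1
    var = seq[pos - 1]
    ref = rng.choice(sorted(set("ACGT") - {var}))
    return SnvRecord(
        id=rec_id, sequence=seq, snv_pos=pos, ref_base=ref, var_base=var, frame_offset=0
    )
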