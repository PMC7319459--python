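"""Classification of simulated edit outcomes into correction scenarios.

A precise correction restores the reference DNA exactly. When the DNA cannot
be restored but the translated protein can, the outcome is a synonymous
correction, sub-typed by what happened at the SNV itself:

* multiple_bases_synonymous — the SNV reverted to the reference base, but
  bystander positions in the window also changed (synonymously);
* on_target_synonymous — the SNV changed to a third base whose codon still
  encodes the reference amino acid;
* bystander_synonymous — the SNV base is untouched; a bystander edit inside
  its codon restores the reference amino acid (the route that rescues
  transversion mutations, which no transition chemistry can revert).

Protein comparison spans the full in-frame translation of the provided
sequence, so a window edit that lands in a neighboring codon and changes its
amino acid disqualifies the result.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

from .editors import EditorRegistry
from .placement import EditOutcome, SnvRecord, enumerate_placements, simulate_edit
from .seqcore import translate

__all__ = [
    "SCENARIOS",
    "CorrectionResult",
    "classify_outcome",
    "find_corrections",
    "results_to_rows",
    "results_to_tsv",
    "results_to_json",
]

SCENARIOS = (
    "precise",
    "multiple_bases_synonymous",
    "on_target_synonymous",
    "bystander_synonymous",
    "none",
)

_SYNONYMOUS = frozenset(SCENARIOS[1:4])


@dataclass(frozen=True)
class CorrectionResult:
    outcome: EditOutcome
    scenario: str
    reference_sequence: str
    edited_protein: str
    reference_protein: str
    variant_protein: str
    snv_base_after_edit: str
    snv_pos: int  # 1-based, from the source record

    @property
    def is_precise(self) -> bool:
        return self.scenario == "precise"

    @property
    def is_synonymous(self) -> bool:
        return self.scenario in _SYNONYMOUS

    @property
    def bystander_count(self) -> int:
        """Changed positions other than the SNV itself."""
        return sum(1 for p in self.outcome.changed_positions if p != self.snv_pos)


def classify_outcome(outcome: EditOutcome, snv: SnvRecord) -> CorrectionResult:
    """Assign a correction scenario to one edit outcome.

    Decision order: full DNA match first (precise); otherwise full protein
    match splits by the SNV base after editing — reference base (multiple
    bases synonymous), a third base (on-target synonymous), or still the
    variant base (bystander synonymous); anything else is no correction.
    """
    if outcome.placement is None or len(outcome.edited_sequence) != len(snv.sequence):
        raise ValueError("outcome does not derive from the given record")
    reference = snv.reference_sequence
    edited = outcome.edited_sequence
    frame = snv.frame_offset
    edited_protein = translate(edited, frame)
    reference_protein = translate(reference, frame)
    variant_protein = translate(snv.sequence, frame)
    snv_after = edited[snv.snv_pos - 1]
    if edited == reference:
        scenario = "precise"
    elif edited_protein == reference_protein:
        if snv_after == snv.ref_base:
            scenario = "multiple_bases_synonymous"
        elif snv_after != snv.var_base:
            scenario = "on_target_synonymous"
        else:
            scenario = "bystander_synonymous"
    else:
        scenario = "none"
    return CorrectionResult(
        outcome=outcome,
        scenario=scenario,
        reference_sequence=reference,
        edited_protein=edited_protein,
        reference_protein=reference_protein,
        variant_protein=variant_protein,
        snv_base_after_edit=snv_after,
        snv_pos=snv.snv_pos,
    )


def find_corrections(
    snv: SnvRecord,
    registry: EditorRegistry,
    *,
    include_minor: bool = True,
) -> list[CorrectionResult]:
    """Run the full pipeline for one SNV: enumerate placements, simulate each
    edit, classify, and keep actual corrections.

    Results are partitioned precise-first (stable within each part). Outcomes
    that change nothing are dropped — a placement whose major window holds no
    source base reports no correction. Placements where the SNV is reachable
    only through a minor window are kept (flagged ``minor_window_match``)
    unless ``include_minor`` is false.
    """
    results: list[CorrectionResult] = []
    for placement in enumerate_placements(snv, registry):
        if not include_minor and placement.snv_window == "minor":
            continue
        outcome = simulate_edit(placement, snv)
        if not outcome.changed_positions:
            continue
        result = classify_outcome(outcome, snv)
        if result.scenario != "none":
            results.append(result)
    precise = [r for r in results if r.is_precise]
    synonymous = [r for r in results if not r.is_precise]
    return precise + synonymous


# --- serialization ---------------------------------------------------------

_COLUMNS = (
    "id",
    "editor",
    "strand",
    "protospacer",
    "pam",
    "snv_distance_from_pam",
    "window",
    "scenario",
    "edited_window_sequence",
    "bystander_count",
)


def _edited_window_sequence(result: CorrectionResult, snv: SnvRecord) -> str:
    """The edited major-window subsequence, read on the protospacer strand."""
    from .placement import _window_positions, _working_strand  # local import, no cycle
    from .seqcore import reverse_complement

    placement = result.outcome.placement
    editor = placement.editor
    n = len(snv.sequence)
    if placement.strand == "+":
        edited_w = result.outcome.edited_sequence
        proto_start = placement.protospacer_start - 1
    else:
        edited_w = reverse_complement(result.outcome.edited_sequence)
        proto_start = n - placement.protospacer_end
    idxs = [i for i in _window_positions(editor, proto_start, editor.major_window) if 0 <= i < n]
    return "".join(edited_w[i] for i in idxs)


def results_to_rows(snv: SnvRecord, results: list[CorrectionResult]) -> list[dict]:
    rows = []
    for r in results:
        p = r.outcome.placement
        rows.append(
            {
                "id": snv.id,
                "editor": p.editor.name,
                "strand": p.strand,
                "protospacer": f"{p.protospacer_start}-{p.protospacer_end}",
                "pam": p.pam_site,
                "snv_distance_from_pam": p.snv_distance_from_pam,
                "window": p.snv_window,
                "scenario": r.scenario,
                "edited_window_sequence": _edited_window_sequence(r, snv),
                "bystander_count": r.bystander_count,
            }
        )
    return rows


def results_to_tsv(snv_results: list[tuple[SnvRecord, list[CorrectionResult]]]) -> str:
    """Tab-separated report, header row, '.' for empty fields."""
    buf = io.StringIO()
    buf.write("\t".join(_COLUMNS) + "\n")
    for snv, results in snv_results:
        for row in results_to_rows(snv, results):
            buf.write("\t".join(str(row[c]) if row[c] != "" else "." for c in _COLUMNS) + "\n")
    return buf.getvalue()


def results_to_json(snv_results: list[tuple[SnvRecord, list[CorrectionResult]]]) -> str:
    payload = [
        {"record": snv.id, "corrections": results_to_rows(snv, results)}
        for snv, results in snv_results
    ]
    return json.dumps(payload, indent=2)
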