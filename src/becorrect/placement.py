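"""Guide placement enumeration and deterministic edit simulation.

For an SNV embedded in a variant-bearing sequence, every (editor, strand,
protospacer start) combination is tested: the PAM must match on the
protospacer strand and the SNV must fall in the editor's major or minor
activity window. A matching placement is then simulated deterministically:
every source base (C for CBEs, A for ABEs, on the protospacer strand) inside
the MAJOR window is converted, all at once; source bases in minor windows are
flagged but left unchanged, reflecting the much lower editing rates there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .editors import FIVE_PRIME, THREE_PRIME, BaseEditor, EditorRegistry
from .seqcore import SequenceError, iupac_match, normalize_dna, reverse_complement

__all__ = ["SnvRecord", "GuidePlacement", "EditOutcome", "enumerate_placements", "simulate_edit"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnvRecord:
    """A variant-bearing coding sequence with 1-based SNV coordinates.

    ``sequence`` carries the VARIANT allele; ``ref_base``/``var_base`` are on
    the same strand as ``sequence``. ``frame_offset`` is the 0-based index of
    the first complete codon. For a full placement scan the SNV should have at
    least (max gRNA length + max PAM length) flanking bases on each side;
    shorter flanks simply truncate the scan.
    """

    id: str
    sequence: str
    snv_pos: int  # 1-based position of the variant base
    ref_base: str
    var_base: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_dna(self.sequence))
        object.__setattr__(self, "ref_base", normalize_dna(self.ref_base, what="ref_base"))
        object.__setattr__(self, "var_base", normalize_dna(self.var_base, what="var_base"))
        if len(self.ref_base) != 1 or len(self.var_base) != 1:
            raise SequenceError("ref_base and var_base must be single bases")
        if self.ref_base == self.var_base:
            raise SequenceError("ref_base and var_base must differ")
        if not 1 <= self.snv_pos <= len(self.sequence):
            raise SequenceError(
                f"snv_pos {self.snv_pos} outside sequence of length {len(self.sequence)}"
            )
        if self.sequence[self.snv_pos - 1] != self.var_base:
            raise SequenceError(
                f"sequence has {self.sequence[self.snv_pos - 1]!r} at snv_pos "
                f"{self.snv_pos}, expected var_base {self.var_base!r}"
            )
        if self.frame_offset not in (0, 1, 2):
            raise SequenceError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")

    @property
    def reference_sequence(self) -> str:
        """The input sequence with the variant base replaced by the reference."""
        i = self.snv_pos - 1
        return self.sequence[:i] + self.ref_base + self.sequence[i + 1 :]


@dataclass(frozen=True)
class GuidePlacement:
    """One (editor, strand, protospacer) placement whose window covers the SNV.

    All coordinates are 1-based inclusive on the INPUT sequence; ``pam_site``
    is the observed PAM text read on the protospacer strand.
    """

    editor: BaseEditor
    strand: str  # '+' or '-'
    protospacer_start: int
    protospacer_end: int
    pam_start: int
    pam_end: int
    pam_site: str
    snv_window: str  # 'major' or 'minor'
    snv_distance_from_pam: int


@dataclass(frozen=True)
class EditOutcome:
    """The deterministically edited sequence for one placement.

    ``edited_sequence`` is on the same strand/coordinates as the input.
    ``minor_bystander_flag`` marks source bases present in minor windows
    (possible low-rate edits, not applied); ``minor_window_match`` marks
    placements where the SNV itself is only reachable through a minor window.
    """

    placement: GuidePlacement
    edited_sequence: str
    changed_positions: tuple[int, ...]  # 1-based, input-sequence coordinates
    minor_bystander_flag: bool
    minor_window_match: bool


def _working_strand(snv: SnvRecord, strand: str) -> tuple[str, int]:
    """Return (sequence, 0-based SNV index) on the requested strand."""
    if strand == "+":
        return snv.sequence, snv.snv_pos - 1
    return reverse_complement(snv.sequence), len(snv.sequence) - snv.snv_pos


def _window_positions(editor: BaseEditor, proto_start: int, window: tuple[int, int]):
    """0-based working-strand indices covered by a distance window, 5'->3'."""
    lo, hi = window
    if editor.pam_side == THREE_PRIME:
        pam_adjacent = proto_start + editor.grna_length - 1  # distance 1
        return range(pam_adjacent - hi + 1, pam_adjacent - lo + 2)
    pam_adjacent = proto_start  # FIVE_PRIME: distance counts into the protospacer
    return range(pam_adjacent + lo - 1, pam_adjacent + hi)


def _distance_from_pam(editor: BaseEditor, proto_start: int, index: int) -> int:
    if editor.pam_side == THREE_PRIME:
        return proto_start + editor.grna_length - index
    return index - proto_start + 1


def enumerate_placements(snv: SnvRecord, registry: EditorRegistry) -> list[GuidePlacement]:
    """Every placement of every editor, on both strands, whose PAM matches and
    whose major or minor window covers the SNV.

    All editors are tried regardless of the SNV's substitution type: window
    and PAM criteria are purely positional, which is what makes on-target and
    bystander rescues of transversions discoverable. Placements whose
    protospacer or PAM would extend past a sequence end are skipped.
    """
    n = len(snv.sequence)
    placements: list[GuidePlacement] = []
    truncated_editors: list[str] = []
    for editor in registry:
        L = editor.grna_length
        P = len(editor.pam)
        per_editor: list[tuple[tuple, GuidePlacement]] = []
        truncated = False
        for strand in "+-":
            seq, snv_idx = _working_strand(snv, strand)
            # protospacer start range so the SNV can be inside the protospacer
            lo_start = max(0, snv_idx - L + 1)
            hi_start = min(snv_idx, n - L)
            if snv_idx - L + 1 < 0 or snv_idx + L > n:
                truncated = True
            for s in range(lo_start, hi_start + 1):
                if editor.pam_side == THREE_PRIME:
                    pam_lo, pam_hi = s + L, s + L + P
                else:
                    pam_lo, pam_hi = s - P, s
                if pam_lo < 0 or pam_hi > n:
                    truncated = True
                    continue
                pam_text = seq[pam_lo:pam_hi]
                if not iupac_match(editor.pam, pam_text):
                    continue
                d = _distance_from_pam(editor, s, snv_idx)
                if editor.in_major(d):
                    window = "major"
                elif editor.in_minor(d):
                    window = "minor"
                else:
                    continue
                if strand == "+":
                    proto = (s + 1, s + L)
                    pam = (pam_lo + 1, pam_hi)
                else:  # map working-strand (revcomp) coords back to input
                    proto = (n - (s + L) + 1, n - s)
                    pam = (n - pam_hi + 1, n - pam_lo)
                placement = GuidePlacement(
                    editor=editor,
                    strand=strand,
                    protospacer_start=proto[0],
                    protospacer_end=proto[1],
                    pam_start=pam[0],
                    pam_end=pam[1],
                    pam_site=pam_text,
                    snv_window=window,
                    snv_distance_from_pam=d,
                )
                per_editor.append(((0 if strand == "+" else 1, proto[0]), placement))
        if truncated:
            truncated_editors.append(editor.name)
        per_editor.sort(key=lambda t: t[0])
        placements.extend(p for _, p in per_editor)
    if truncated_editors:
        logger.debug(
            "record %s: scan truncated by sequence ends for %d editor(s): %s",
            snv.id,
            len(truncated_editors),
            ", ".join(truncated_editors),
        )
    return placements


def simulate_edit(placement: GuidePlacement, snv: SnvRecord) -> EditOutcome:
    """Apply the deterministic major-window edit for one placement.

    Every protospacer-strand source base in the major window converts (all or
    nothing, respecting the editor's context rule); minus-strand edits map
    back to the input strand as complement conversions (a C>T edit on the
    minus strand appears as G>A on the input strand). Minor-window source
    bases set ``minor_bystander_flag`` only.
    """
    editor = placement.editor
    n = len(snv.sequence)
    seq, _ = _working_strand(snv, placement.strand)
    if placement.strand == "+":
        proto_start = placement.protospacer_start - 1
    else:
        proto_start = n - placement.protospacer_end
    if placement.protospacer_end - placement.protospacer_start + 1 != editor.grna_length:
        raise ValueError("placement/editor mismatch: protospacer length != grna_length")

    def is_editable(idx: int) -> bool:
        if seq[idx] != editor.source_base:
            return False
        if editor.context_rule is not None:
            # context base is the 5'-adjacent base on the protospacer strand;
            # unavailable at the sequence edge -> treated as not satisfied
            if idx == 0 or seq[idx - 1] != editor.context_rule:
                return False
        return True

    chars = list(seq)
    changed_w: list[int] = []
    for idx in _window_positions(editor, proto_start, editor.major_window):
        if 0 <= idx < n and is_editable(idx):
            chars[idx] = editor.product_base
            changed_w.append(idx)
    minor_bystander = any(
        0 <= idx < n and is_editable(idx)
        for w in editor.minor_windows
        for idx in _window_positions(editor, proto_start, w)
    )
    edited_w = "".join(chars)
    if placement.strand == "+":
        edited = edited_w
        changed = tuple(i + 1 for i in changed_w)
    else:
        edited = reverse_complement(edited_w)
        changed = tuple(sorted(n - i for i in changed_w))
    return EditOutcome(
        placement=placement,
        edited_sequence=edited,
        changed_positions=changed,
        minor_bystander_flag=minor_bystander,
        minor_window_match=placement.snv_window == "minor",
    )
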