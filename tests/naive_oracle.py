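"""Naive brute-force reference for placement search, independent of the
package's scan: slides every protospacer start on both strands and checks the
PAM and window criteria one base at a time with its own IUPAC table."""

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_placements(snv, registry):
    """Every (editor name, strand, 1-based protospacer start on the input
    sequence, window kind, SNV distance from PAM) satisfying the criteria."""
    n = len(snv.sequence)
    found = []
    for editor in registry:
        L, P = editor.grna_length, len(editor.pam)
        for strand in "+-":
            work = snv.sequence if strand == "+" else revcomp(snv.sequence)
            i = snv.snv_pos - 1 if strand == "+" else n - snv.snv_pos
            for s in range(0, n - L + 1):
                if not (s <= i < s + L):
                    continue  # SNV outside the protospacer
                if editor.pam_side == "three_prime":
                    pam_lo, pam_hi = s + L, s + L + P
                    d = s + L - i
                else:
                    pam_lo, pam_hi = s - P, s
                    d = i - s + 1
                if pam_lo < 0 or pam_hi > n:
                    continue
                pam = work[pam_lo:pam_hi]
                if not all(b in IUPAC[c] for c, b in zip(editor.pam, pam)):
                    continue
                lo, hi = editor.major_window
                if lo <= d <= hi:
                    window = "major"
                elif any(a <= d <= b for a, b in editor.minor_windows):
                    window = "minor"
                else:
                    continue
                start_input = s + 1 if strand == "+" else n - (s + L) + 1
                found.append((editor.name, strand, start_input, window, d))
    return found


def naive_ea3a_edit(protospacer_context: str, window_idx: range) -> str:
    """Base-by-base TC-context scan: convert C to T only when the previous
    base is T, within the given indices."""
    chars = list(protospacer_context)
    for idx in window_idx:
        if idx > 0 and chars[idx] == "C" and protospacer_context[idx - 1] == "T":
            chars[idx] = "T"
    return "".join(chars)
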