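# becorrect

Find base editors that can correct a pathogenic point mutation — either
precisely, or by exploiting codon degeneracy when precise reversal is
chemically impossible.

## The problem

CRISPR base editors (BEs) install single-nucleotide *transitions* without a
double-strand break: cytosine base editors (CBEs) deaminate C→T and adenine
base editors (ABEs) convert A→G on the protospacer strand; targeting the
complementary strand yields G→A and T→C. Each editor only works where its
Cas protein finds a PAM, and only deaminates bases inside an *activity
window* at a fixed distance from that PAM — efficiently in the major window,
weakly in minor windows. Within the major window every target base converts,
so bystander C/A bases are co-edited.

This makes experiment design a search problem: given a disease-causing SNV
inside a coding sequence, which of the published editors (the package ships
26: 17 CBEs and 9 ABEs, plus support for user-defined ones) has a matching
PAM placement putting the SNV in its window, and what does the resulting
edit do to the protein? `becorrect` enumerates every (editor, strand,
protospacer) placement, simulates the deterministic deamination edit, and
classifies the outcome:

* **precise** — edited DNA equals the reference allele;
* **multiple bases synonymous** — the SNV reverts and co-edited bystanders
  change the DNA silently;
* **on-target synonymous** — the SNV converts to a third base whose codon
  still encodes the reference amino acid;
* **bystander synonymous** — the SNV stays wrong but a bystander edit in its
  codon restores the reference amino acid.

The last two rescue *transversion* mutations, which no transition chemistry
can reverse at the DNA level. Exhaustive codon-level enumeration shows
exactly five transversion-derived amino-acid substitutions are recoverable
this way — I>M, L>F, R>G, R>W and R>\* — while serine, despite six codons,
is never recoverable because its AGY and TCN codon families differ at two
positions.

## Worked example

The classic case: variant `ACTCTA` (Thr,Leu) where the reference first codon
is `ATT` (Ile). The variant C sits at distance 16 from an NGG PAM; the BE3
window (13–17) also covers a bystander C whose edit is silent:

```
$ becorrect match \
    --seq GATGATGATGATACTCTAGATGATGATGAAGGTGATGATGATGATGATGATGATGATGAT \
    --pos 14 --ref T --var C --frame 0
id     editor                               strand  protospacer  pam   snv_distance_from_pam  window  scenario                   edited_window_sequence  bystander_count
query  VQR-BE3                              +       4-23         TGAT  10                     major   precise                    GATGATAT                0
query  Target-AID-NG                        +       11-30        GG    17                     major   precise                    TAT                     0
query  xBE3                                 +       7-26         TG    13                     major   precise                    GATAT                   0
query  BE1/BE2/BE3/HF-BE3/BE4(max)/BE4-Gam  +       10-29        AGG   16                     major   multiple_bases_synonymous  ATTTT                   1
...
```

(16 rows total; output is tab-separated — aligned here for readability.)
Precise corrections come first: three editors whose narrower windows (or
PAM offsets) cover only the SNV cytosine restore `ATTCTA` exactly. The BE3
row is the textbook multiple-bases synonymous correction: both window Cs
convert, `ACTCTA` → `ATTTTA`, and the protein reads Ile,Leu — identical to
the reference — with one silent bystander change.

Other subcommands: `batch` (TSV of SNVs), `cohort` (variant table →
exclusion filters, repairability fractions and a per-amino-acid recovery
matrix), `editors list|validate`, `fixtures generate` (synthetic cohorts
with planted ground truth).

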