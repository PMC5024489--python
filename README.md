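# studyid

Guaranteed-unique, block-structured, layered identifiers for
epidemiologic and clinical studies — as a Python library and a small
CLI.

Study data management needs more than serial numbers: IDs must be
generated in batches that never collide with earlier ones, carry
organizational codes (study center, recruitment track, visit) directly
in the string, protect against typing errors with a check digit, and —
for data protection — come in *layers*: a personal-data ID (ID-P), a
study-data ID (ID-S) and a temporary ID (ID-T) that links them only
through key-pair files, plus per-partner external IDs (ID-E). `studyid`
generates all of these, as plain-text key-pair files and Code 128B
barcode strings, for study personnel and data managers who run a
pseudonymization workflow.

## The model in brief

An ID is a fixed-width string of blocks in any order — center `[C]`,
track `[T]`, random number `[N]`, visit `[V]`, check digit `[X]` —
with only `[N]` mandatory. For number length *k* (2–9), the k-digit
range is split into thirds:

* ID-P numbers ∈ [1·10^(k−1), 4·10^(k−1))
* ID-S numbers ∈ [4·10^(k−1), 7·10^(k−1))
* ID-T numbers ∈ [7·10^(k−1), 10·10^(k−1))

giving 3·10^(k−1) unique numbers per layer (30 000 at k=5,
300 000 000 at k=9, i.e. 9·10^8 unique IDs over the three layers).
Uniqueness is guaranteed, not merely probable: every draw is checked
against all numbers ever issued in the study, reconstructed from the
files on disk. Check digits come in four flavours — parity, weighted
parity, a Damm (2004) quasigroup walk and a Gumm-style mod-11 variant —
covering increasingly strong error-detection classes (see
`docs/methods.md`).

## Worked example

Create a two-track study with 5-digit numbers, a visit block and a
Damm check digit:

```
$ studyid create --study AGING --layout T,N,V,X --k 5 --tracks "1;2" \
      --n "4;3" --check-algorithm damm --visit 1 --seed 42
wrote AGING_IDP_IDT_T=1_N=4_Baseline.txt (4 rows)
wrote AGING_IDS_IDT_T=1_N=4_Baseline.txt (4 rows)
wrote AGING_IDP_IDT_T=2_N=3_Baseline.txt (3 rows)
wrote AGING_IDS_IDT_T=2_N=3_Baseline.txt (3 rows)

$ cat "AGING/AGING_IDP_IDT_T=1_N=4_Baseline.txt"
13727901	18647813
12288600	19061814
13999705	17290011
12101600	18351915
```

Read one row: `13727901` is track `1`, random number `37279` (from the
P-interval [10000, 40000)), visit `0` — personal IDs always render
visit 0 — and Damm check digit `1`; its partner `18647813` is the
temporary ID with a number from the T-interval and visit `1`. The
matching study file carries the same ID-T values but shuffled rows, so
file order cannot re-associate ID-P with ID-S:

```
$ cat "AGING/AGING_IDS_IDT_T=1_N=4_Baseline.txt"
15213615	18351915
16310410	17290011
14777114	19061814
14238718	18647813
```

Follow-up visit and external project IDs:

```
$ studyid add-visit --dir AGING --visit A
$ cat "AGING/AGING_IDS_IDSA_T=1_N=4_V=A.txt"
15213615	152136A3
16310410	163104A5
14777114	147771A1
14238718	142387A2

$ studyid external --dir AGING --project EXT --seed 7
$ cat "AGING/AGING_IDS_IDE_T=1_N=4_Prj=EXT.txt"
14238718	EXT5417887
14777114	EXT7334820
15213615	EXT5904239
16310410	EXT2535500
```

The visit file keeps each study number and swaps only the visit
character (check digit recomputed: `15213615` → `152136A3`). External
IDs are the project code, a 6-digit number (one digit longer than k=5,
drawn from a project-private pool) and the same style of check digit.
Every file has a `_barcode` twin holding Code 128B font strings, e.g.
`Ì13727901|Î` for the first personal ID. Batch extension
(`studyid add-ids`), new tracks (`studyid add-track`), check-digit
validation (`studyid verify`) and a summary (`studyid info`) complete
the workflow; `studyid info --dir AGING` reports 7 numbers used and
29 993 remaining per layer for this study.

The same operations are available as library functions
(`studyid.create_ids`, `add_ids`, `add_visit`, `add_track`,
`generate_external`, `load_study`, …).

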