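# Methods

## The problem

Epidemiologic and clinical studies need participant identifiers that are
(a) guaranteed unique within the study, (b) structured — carrying
organizational codes such as study center, recruitment track and visit
directly in the ID string — and (c) layered, so that personal data and
study data are keyed by different IDs that can only be linked through
key-pair files held by a trusted party. `studyid` implements this as a
library plus a thin CLI.

## Identifier model

Every ID is a fixed-width concatenation of blocks in a user-chosen
order: center `[C]`, track `[T]`, random number `[N]`, visit `[V]` and
check digit `[X]`. Only `[N]` is mandatory; at most one block of each
kind is allowed, because fixed-width parsing requires unambiguous
positions. Center and track codes may be any alphanumeric string, but
all tracks must share one width (again for parseability); visits are a
single character from `1-9` or letters excluding lowercase `i`, `e`,
`o` (case sensitive, so `I`/`E`/`O` remain legal). The check digit may
sit anywhere in the layout; it is always computed over all *other*
rendered characters in order and substituted into its own position.

## Layers and number pools

For number length `k` (2–9), the k-digit range `[10^(k-1), 10^k)` is
split into three equal thirds:

| layer | range | role |
|---|---|---|
| P | `[1·10^(k-1), 4·10^(k-1))` | personal-data ID |
| S | `[4·10^(k-1), 7·10^(k-1))` | study-data ID |
| T | `[7·10^(k-1), 10·10^(k-1))` | temporary linkage ID |

so each layer owns `3·10^(k-1)` numbers (30 000 at k=5; 300 000 000 at
k=9) and the layer of any number is recoverable from its value alone.
External IDs (layer E, one independent pool per external project) draw
from the full `(k+1)`-digit range and therefore cannot collide with any
study layer. The personal ID always renders visit `0`; study and
temporary IDs carry the configured visit.

The exponent convention is `10^(k-1)`, i.e. `k` is the digit length of
the number; the per-layer capacity follows as `3·10^(k-1)`.

## Uniqueness and randomness

Numbers are drawn by rejection sampling against the set of all numbers
ever issued in the study (reconstructed from the key-pair files on
disk, including archived `.old` batches, so the guarantee survives
program restarts). When a request exceeds half of the remaining pool,
the draw switches to `random.sample` without replacement over the
enumerated residual set: output remains uniform and unique, but the
near-exhaustion quadratic slowdown of pure rejection is avoided. The
switch enumerates the residual set in memory, which is fine for the
supported pool sizes but is the reason huge `k=9` requests should be
issued in batches.

Randomness comes from seedable, labelled streams (`RandomSource`):
number draws, row shuffles and per-project external draws each use a
distinct stream label derived from one base seed, so a seeded run is
byte-reproducible while the row shuffle cannot be reconstructed from
the draw sequence. Without a seed, streams initialize from system
entropy (deliberately not from a clock-derived value, which is weak and
collision-prone).

## Check digits

Four schemes (`check_digits`):

* **parity** — `(Σ value_i) mod 10`. Letters contribute their ASCII
  code (`A` → 65), digits their value. Detects any single substitution
  whose value change is nonzero mod 10; detects no transpositions.
* **weighted parity** — `(Σ i·value_i) mod 10`, positions 1-based from
  the left (a 0-based origin would leave the leading character
  unprotected). Additionally detects every adjacent transposition of
  distinct digits; misses non-adjacent swaps whose digit difference
  is 5.
* **Damm (2004)** — interim-digit walk through the published totally
  anti-symmetric quasigroup of order 10 (hard-coded; the anti-symmetry
  axioms themselves are unit-tested). Detects all single-digit errors
  and all adjacent transpositions; always yields a digit 0–9.
* **Gumm-style mod-11** — a documented variant: check digit `c` with
  `(Σ 2^i·value_i + c) ≡ 0 (mod 11)`, weights 1-based. Because the
  powers of two are distinct and invertible mod 11, it detects all
  substitutions and *all* transpositions for payloads up to 9
  characters. When `c` would be 10 there is no single-digit check; the
  generator then discards the candidate number and draws another
  (REDRAW), keeping every emitted ID one fixed width. The rejected
  number stays burned, which costs a negligible fraction of the pool
  (≈1/11 of candidates).

Letters feed the table-based schemes as `ASCII mod 10` so the
quasigroup domain stays valid; parity schemes use the full ASCII value.

Known limitation: under the mod-11 scheme a *visit extension* can hit
REDRAW — the number is fixed at that point, so the affected IDs cannot
carry that visit; the task fails loudly listing them rather than
emitting a two-digit check.

## Tasks and files

All output is plain-text, two tab-separated columns, one pair per line,
in a directory named after the study, with the configuration persisted
as versioned XML (`config.xml`) alongside. File names follow the fixed
templates

    STUDY_IDP_IDT_T=<track>_N=<n>_Baseline.txt
    STUDY_IDS_IDT_T=<track>_N=<n>_Baseline.txt
    STUDY_IDS_IDS<v>_T=<track>_N=<n>_V=<v>.txt
    STUDY_IDS_IDE_T=<track>_N=<n>_Prj=<project>.txt

with a `_barcode` companion for each (same rows, both columns encoded
as Code 128B font strings) and `.txt` → `.old` archival on batch
extension (`.old1`, `.old2`, … on collision — prior batches are never
destroyed).

* **create** draws an (ID-P, ID-S, ID-T) triple per participant slot;
  the (ID-P, ID-T) file keeps creation order while the (ID-S, ID-T)
  file is row-shuffled with an independent stream, so file order cannot
  re-associate the two sides.
* **add-ids** extends a study (per track) with numbers disjoint from
  everything previously issued, writing merged files with the new total
  in the name; it fails before touching any file if the remaining pool
  is too small. Creation validates strictly (`requested < capacity`);
  extension may fill the pool completely.
* **add-visit** re-issues each study ID with only the visit character
  replaced (check digit recomputed); no new numbers. Output is an
  (ID-S, ID-S′) file per track.
* **add-track** registers a new arm with empty `N=0` files and updates
  the stored configuration; a following add-ids populates it.
* **external** gives each study ID an external ID: project code +
  unique `(k+1)`-digit number + check digit (only if the study IDs
  carry one, same algorithm). Each project has its own independent
  pool and stream, so two external partners cannot link records via
  their ID-Es; rows are written sorted by ID-S. Random parts are unique
  within a project; across projects the prefix disambiguates.

## Code 128B

`barcode128` emits the symbol sequence `[104 (Start B), ASCII−32 per
character, checksum, 106 (Stop)]` with checksum
`(104 + Σ i·value_i) mod 103`, and a printable font string using the
de-facto barcode-font mapping (values 0–94 → ASCII 32–126, 95–106 →
ASCII 195–206), chosen because it is invertible and printable with
standard Code 128 fonts. No image rendering — the font string is the
deliverable. Subsets A/C, code-set switching and GS1 identifiers are
out of scope.

## Fixtures and what they do (not) show

`make_fixture_study("small")` builds a one-track k=3 study of 10 IDs
with a parity check; `"augur_like"` mimics a prospective elderly-cohort
recruitment: three tracks (registry-, clinic-based, volunteers) encoded
in the ID, a visit block, a Damm check and 140 slots, with number
length and sample size scaled down (k=4, 140 instead of five-digit
numbers and tens of thousands of slots) so the fixture builds in
milliseconds. Scaling down exercises every code path — interval
arithmetic, uniqueness, shuffling, check digits — identically to full
size; what it does not probe is wall-clock behaviour of very large
draws near pool exhaustion at k≥6. Fixtures disable the audit log
(whose lines carry wall-clock timestamps) so equal seeds give
byte-identical directories.

Test problem sizes follow the same principle: exhaustive error-grids
run at 3–4 digit payloads where the claimed detection classes can be
verified completely, and pool-exhaustion scenarios run at k=2–3 where
the whole pool fits in a few hundred numbers.

## Numerical/behavioural choices

* Duplicate checking uses hash sets; the contract is set membership,
  and outputs are unaffected by the lookup structure.
* `validate_config` collects *all* violations rather than failing fast,
  mirroring a form-style CHECK step; tasks never write partial output
  on a failed validation (files are written to a temp name and renamed).
* The audit log (`audit.log`) appends one line per task with timestamp,
  task name, parameters and output files — a minimal traceability
  record for study data management.
* The CLI replaces a GUI progress bar with a textual percentage at
  ≥1 % increments on stderr.

## Limitations

* No GUI, no linkage-unit workflow automation (key-file transfer and
  ID-T deletion are organizational procedures, not computation).
* One barcode symbology (Code 128B); no raster rendering.
* Pool state is implicit in the study directory; concurrent writers to
  one study directory are not coordinated.
* Encoding participant characteristics in track codes is possible but
  discouraged: structured IDs are pseudonyms, and over-coding risks
  re-identification.
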