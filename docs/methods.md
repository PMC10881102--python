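# Methods

## What the harness does

`wftest` treats one pipeline execution as one test case. A case is judged
by (1) engine completion — the engine's exit status, recorded always, with
any nonzero status failing the case before assertions run — and (2) an
ordered list of output assertions evaluated only after successful
completion. All assertions are always evaluated; there is no short-circuit
after the first failure, because a complete report is worth more than the
few saved digest computations. Cases execute sequentially in file order,
which keeps logs and reports deterministic; parallel execution was
deliberately left out.

The harness never interprets the workflow itself. It assembles the engine
command line, delegates execution to a subprocess with stdout/stderr
captured to `<case>.stdout.log` / `<case>.stderr.log` next to the test
file, and inspects only exit status and output files. The emitted surface
is `-c` (repeatable config files), `run <script-or-org/repo>`,
`-profile p1,p2,...`, `-params-file`, `--<output-param> <dir>`, and
`-w <workdir>`. The suite-wide config is placed before case-level configs
because the engine lets later `-c` files win, mirroring the harness's own
override semantics at the engine level.

## Settings hierarchy

Per field, the value comes from the highest-precedence source that set it:

| field        | env var        | case | global | built-in default  |
|--------------|----------------|------|--------|-------------------|
| temp_dir     | `WFTEST_TEMP`  | yes  | yes    | `wftest-work`     |
| nf_config    | —              | yes  | yes    | none              |
| remove_temp  | —              | yes  | yes    | `false`           |
| clean_logs   | —              | yes  | yes    | `false`           |
| output base  | `WFTEST_OUTPUT`| —    | —      | `wftest-output`   |

Environment variables beat file contents by design: their purpose is
per-developer paths on shared test definitions, and a value that could be
overridden from the committed file would defeat that. Resolution is total —
every field comes out concrete, so downstream code never handles "unset".

Each case's output directory is `<base>/<case name>`. The per-case
subdirectory prevents cases from clobbering or cross-matching each other's
outputs, and is the directory that `actual` glob patterns resolve against
and that the engine receives through the pipeline-defined parameter named
by `output_directory_param_name` (passed in the double-dash pipeline-
parameter form, since the output parameter is defined by the pipeline, not
the engine).

## Assertion semantics and numerical choices

- **Status taxonomy.** `pass`/`fail` are reserved for comparisons that ran;
  `error` marks infrastructure problems (missing file, ambiguous or empty
  glob resolution, non-executable comparator). The one deliberate
  exception: during snapshot comparison a file missing from the output
  directory is a `fail`, because relative to the recorded reference run the
  pipeline regressed — that is a result, not a broken harness.
- **Checksums** digest whole files, streamed in 1 MiB chunks so memory use
  is constant in file size; md5 is the default, sha512 available. The
  comparison is digest-of-actual vs digest-of-expect, so expected artifacts
  are stored as plain files, not digest strings.
- **Glob resolution** must be unique: zero or multiple matches are both
  errors. Ambiguity is never silently resolved by picking the first match.
- **Custom comparators** are any executable invoked as
  `script <actual> <expect>`; exit 0 is the portable pass convention, any
  nonzero exit a fail, and the script's output is preserved in the result
  detail.
- **VCF comparison** drops every `#`-prefixed line (meta headers and the
  `#CHROM` column line) and compares the remaining record lines as ordered
  strings, insensitive to a trailing newline. Order-sensitivity is
  intentional: valid VCFs are coordinate-sorted, so a deterministic
  line-wise comparison suffices and no semantic normalization (allele
  atomization, INFO reordering) is attempted. Gzip input is detected by
  magic bytes, not extension, because compression headers embed timestamps
  and extensions are unreliable; comparison always targets decompressed
  content.
- **Snapshots** are YAML manifests (`<case>.snapshot.yaml`) mapping
  output-relative paths to `(algorithm, digest)`. Comparison flags changed
  and vanished entries; files present in the output but absent from the
  manifest are ignored — the manifest records what was asserted, not an
  inventory of the directory.
- **Cleanup** applies only to passing cases: `remove_temp` deletes the
  engine work directory, `clean_logs` the captured log files. Failed cases
  retain everything for debugging regardless of the flags, and deletions
  never touch anything outside the work directory and log locations; a
  failed deletion is a warning, never a test failure.
- **Selection.** With no names, exactly the `enabled` cases run, in file
  order. With names, exactly the named cases run regardless of the flag —
  matching is exact and case-sensitive, duplicates are de-duplicated, and
  execution follows file order, not request order. An unknown name aborts
  the whole suite (exit 2) rather than running a partial selection.
- **Remote script detection** (`is_remote_script`) classifies a reference
  as `organization/repository` when it has exactly one slash, no `./` or
  `/` prefix, and no `.nf` extension. The classification is informational;
  the reference is always passed to the engine verbatim.

## The stub engine and what passing tests show

The package's own test suite runs without any engine installation. The
`fixtures` module generates a stub engine — a plain Python script — that
accepts exactly the command surface the runner emits, writes declared
output files under the directory given by the `--<param>` argument,
optionally records its argv for command-construction checks, and exits with
a configured status. The stub rejects unclassifiable tokens (exit 64), so
it actively validates command syntax rather than swallowing anything.
Declared outputs are written only on exit 0, mimicking a failed run that
produces no final outputs, and a scratch marker is dropped in the work
directory so cleanup behaviour is observable.

The stub emulates the engine's *interface*, not its semantics: no
scheduling, resume, containers, channel evaluation or remote repository
fetching. Passing tests therefore demonstrate that the harness assembles
correct commands, classifies outcomes correctly and validates outputs
faithfully — they say nothing about any particular engine version's
behaviour, which is exactly the separation a harness test should have.
Synthetic VCFs use sorted positions on a single contig with random SNV
alleles; they exercise the comparator's header/record distinction, not
biological realism.

Problem sizes in the test suite and acceptance script — 100 random files
per checksum algorithm, 100 VCF comparator trials split across plain and
gzip, 1000 random hierarchy configurations, 25 random command
constructions — were chosen to exercise each property well past the point
where a systematic defect could hide, while keeping a full run in seconds.
All randomness is seeded; the checksum oracle is GNU coreutils
(`md5sum`/`sha512sum`), independent of the `hashlib` implementation path.

## Known limitations

- Output validation is file-based only; outputs written to databases or
  cloud object stores are out of scope.
- No semantic VCF normalization and no BAM/CRAM comparators; binary
  outputs can still be validated by checksum or custom script.
- One YAML dialect, one document per file; no includes or inheritance
  between test files.
- The report is plain text; there is no JUnit-XML/HTML emitter, so CI
  integration relies on the exit-code contract (0 pass / 1 test failures /
  2 suite error).
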