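# wftest

Automated testing of workflow-engine pipelines (Nextflow-style) from
declarative YAML test definitions.

Bioinformatics pipelines chain many external tools — aligners, variant
callers, statistical post-processing — through an orchestration engine, and
an error in any one step or in the plumbing between steps silently changes
the final outputs. `wftest` gives pipeline developers a test harness in the
spirit of unit-testing frameworks: test cases are declared once in a YAML
file, and the harness then runs the engine per case and validates the
outputs, so every development cycle gets the same checks without manual
setup.

## The model

A test suite is one YAML file with a two-level settings hierarchy:

- a **global** block with suite-wide defaults — engine work directory
  (`temp_dir`, passed to the engine as `-w`), a shared engine config file
  (`nf_config`, passed as `-c` before any case-level configs so those can
  override it), and cleanup flags (`remove_temp`, `clean_logs`);
- a list of **cases**, each naming the workflow script to run (a local path
  or an `organization/repository` reference passed verbatim to the engine),
  its config files, profiles and params-file, and an ordered list of
  assertions. Any global field may be restated on a case to override it.

Environment variables supply per-developer paths without editing the
committed test file and take highest precedence: `WFTEST_OUTPUT` (base
output directory; each case writes under `<base>/<case name>`),
`WFTEST_TEMP` and `WFTEST_LOG_LEVEL`. Resolution per field is

```
environment  >  case override  >  global  >  built-in default
```

Each case is judged in two stages. Engine completion is the implicit first
assertion: a nonzero engine exit fails the case outright (a case with no
assertions is exactly a completion-only test). On success, every declared
assertion runs — none are skipped after a failure, so reports are complete:

- **checksum** — the output file matching the `actual` glob pattern must
  have the same md5 or sha512 digest as the stored `expect` file;
- **script** — any executable taking two arguments (actual file, expected
  file) decides the comparison; exit 0 is a pass, anything else a fail.
  A header-insensitive VCF comparator ships with the package
  (`compare_vcf_records`): it ignores every `#`-prefixed line and compares
  only the variant records, plain or gzipped, which is what you want when
  headers embed dates, versions or command lines;
- **snapshot** — `record_snapshot` stores the digests of a trusted run in a
  `<case>.snapshot.yaml` manifest; `assert_snapshot` validates later runs
  against it, flagging exactly the entries that changed or vanished.

Missing files, unresolvable patterns and non-executable comparators are
reported as `error`, never as `fail`: an infrastructure problem is not a
content mismatch.

## Worked example

Scaffold a project (creates the test directory and two editable templates;
the template case is disabled, so a fresh scaffold runs as a clean no-op):

```console
$ wftest init .
test
test/global.config
test/wftest.yaml
```

Define a case in `test/wftest.yaml`:

```yaml
global:
  temp_dir: ./test/work
  remove_temp: true
cases:
  - name: strelka2-calls
    message: Variant calls from the toy pipeline match the expected set.
    nf_script: ./main.nf
    profiles: [test, docker]
    output_directory_param_name: output_dir
    asserts:
      - actual: "*.vcf"
        expect: ./test/expected/strelka2.vcf
        method: checksum
        algorithm: md5
```

and run it:

```console
$ wftest run --test-file test/wftest.yaml
PASS  strelka2-calls  (engine exit 0, 1/1 assertions passed)
---
1 selected, 1 passed, 0 failed
```

The harness invoked `nextflow run ./main.nf -profile test,docker
--output_dir wftest-output/strelka2-calls -w ./test/work`, resolved
`*.vcf` under the case's output directory, and found its md5 digest equal
to the expected file's. `1 selected, 1 passed, 0 failed` is the suite
summary; the process exit code is 0 (it is 1 when any case fails, 2 on
suite-level errors such as malformed YAML or an unknown case name — the
contract CI systems key on). `wftest run "case a" "case b"` runs exactly
the named cases, even ones disabled by default.

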