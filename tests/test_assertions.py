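"""Checksum, comparator-script, VCF and snapshot assertion behaviour."""

from __future__ import annotations

import random
import subprocess

import pytest

from wftest import (
    AssertionSpec,
    InfrastructureError,
    assert_checksum,
    assert_script,
    assert_snapshot,
    compare_vcf_records,
    compute_checksum,
    evaluate_assertion,
    load_snapshot,
    make_random_file,
    make_random_vcf_records,
    make_vcf,
    record_snapshot,
    resolve_actual,
    snapshot_path,
    write_snapshot,
)

UTILITY = {"md5": "md5sum", "sha512": "sha512sum"}


def reference_digest(path, algorithm):
    """Independent oracle: GNU coreutils checksum utilities."""
    out = subprocess.run(
        [UTILITY[algorithm], str(path)], capture_output=True, text=True, check=True
    )
    return out.stdout.split()[0]


def write_pass_script(path):
    path.write_text("#!/bin/sh\nexit 0\n")
    path.chmod(0o755)
    return path


def write_fail_script(path, code=1):
    path.write_text(f"#!/bin/sh\necho mismatch\nexit {code}\n")
    path.chmod(0o755)
    return path


class TestComputeChecksum:
    @pytest.mark.parametrize("algorithm", ["md5", "sha512"])
    @pytest.mark.parametrize("content", [b"", b"hello\n", b"\x00" * 4096])
    def test_agrees_with_reference_utility(self, tmp_path, algorithm, content):
        path = tmp_path / "f.bin"
        path.write_bytes(content)
        assert compute_checksum(path, algorithm) == reference_digest(path, algorithm)

    @pytest.mark.parametrize("algorithm", ["md5", "sha512"])
    def test_agrees_on_seeded_random_files(self, tmp_path, algorithm):
        rng = random.Random(20)
        for i in range(10):
            path = make_random_file(rng.randrange(2**31), rng.randrange(0, 5000), tmp_path / f"r{i}")
            assert compute_checksum(path, algorithm) == reference_digest(path, algorithm)

    def test_digest_lengths(self, tmp_path):
        path = tmp_path / "f"
        path.write_bytes(b"x")
        assert len(compute_checksum(path, "md5")) == 32
        assert len(compute_checksum(path, "sha512")) == 128

    def test_missing_file_is_infrastructure_error(self, tmp_path):
        with pytest.raises(InfrastructureError, match="ghost"):
            compute_checksum(tmp_path / "ghost", "md5")

    def test_unknown_algorithm_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            compute_checksum(tmp_path, "crc32")


class TestResolveActual:
    def test_unique_match(self, tmp_path):
        (tmp_path / "a.vcf").write_text("x")
        assert resolve_actual("*.vcf", tmp_path).name == "a.vcf"

    def test_ambiguous_match_lists_candidates(self, tmp_path):
        (tmp_path / "a.vcf").write_text("x")
        (tmp_path / "b.vcf").write_text("y")
        with pytest.raises(InfrastructureError, match="a.vcf.*b.vcf"):
            resolve_actual("*.vcf", tmp_path)

    def test_literal_subpath_pattern(self, tmp_path):
        (tmp_path / "out").mkdir()
        target = tmp_path / "out" / "report.txt"
        target.write_text("r")
        assert resolve_actual("out/report.txt", tmp_path) == target

    def test_no_match_is_error(self, tmp_path):
        with pytest.raises(InfrastructureError, match="no actual file"):
            resolve_actual("*.vcf", tmp_path)


class TestAssertChecksum:
    def test_identical_files_pass(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        a.write_bytes(b"same content")
        b.write_bytes(b"same content")
        result = assert_checksum(a, b)
        assert result.status == "pass" and "md5" in result.detail

    def test_single_byte_difference_fails_with_two_digests(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        a.write_bytes(b"content-A")
        b.write_bytes(b"content-B")
        result = assert_checksum(a, b)
        assert result.status == "fail"
        digests = [tok.split("=")[1] for tok in result.detail.split() if "=" in tok]
        assert len(set(digests)) == 2

    def test_missing_expect_is_error_not_fail(self, tmp_path):
        a = tmp_path / "a"
        a.write_bytes(b"x")
        assert assert_checksum(a, tmp_path / "absent").status == "error"

    def test_symmetry(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        a.write_bytes(b"one")
        b.write_bytes(b"two")
        assert assert_checksum(a, b).status == assert_checksum(b, a).status


class TestAssertScript:
    def test_exit_zero_passes(self, tmp_path):
        script = write_pass_script(tmp_path / "ok.sh")
        a, b = tmp_path / "a", tmp_path / "b"
        a.write_text("1")
        b.write_text("2")
        assert assert_script(script, a, b).status == "pass"

    def test_nonzero_exit_fails_and_preserves_output(self, tmp_path):
        script = write_fail_script(tmp_path / "bad.sh")
        a, b = tmp_path / "a", tmp_path / "b"
        a.write_text("1")
        b.write_text("2")
        result = assert_script(script, a, b)
        assert result.status == "fail" and "mismatch" in result.detail

    def test_missing_script_is_error(self, tmp_path):
        a = tmp_path / "a"
        a.write_text("1")
        assert assert_script(tmp_path / "none.sh", a, a).status == "error"

    def test_receives_actual_then_expect(self, tmp_path):
        script = tmp_path / "order.sh"
        script.write_text('#!/bin/sh\ntest "$(basename $1)" = actual && test "$(basename $2)" = expect\n')
        script.chmod(0o755)
        actual, expect = tmp_path / "actual", tmp_path / "expect"
        actual.write_text("a")
        expect.write_text("e")
        assert assert_script(script, actual, expect).status == "pass"


HEADERS = ["##fileformat=VCFv4.2", "##source=callerA", "##contig=<ID=chr21>"]


class TestCompareVcfRecords:
    @pytest.mark.parametrize("gz", [False, True])
    def test_identical_records_different_headers_pass(self, tmp_path, gz):
        records = make_random_vcf_records(seed=7, n_records=5)
        a = make_vcf(records, HEADERS, tmp_path / "a.vcf", gzip=gz)
        b = make_vcf(records, ["##source=callerB"], tmp_path / "b.vcf", gzip=gz)
        assert compare_vcf_records(a, b).status == "pass"

    def test_single_record_mutation_fails_at_that_index(self, tmp_path):
        records = make_random_vcf_records(seed=8, n_records=4)
        mutated = list(records)
        mutated[2] = mutated[2].replace("\tPASS\t", "\tq10\t")
        a = make_vcf(records, HEADERS, tmp_path / "a.vcf")
        b = make_vcf(mutated, HEADERS, tmp_path / "b.vcf")
        result = compare_vcf_records(a, b)
        assert result.status == "fail" and "index 2" in result.detail

    def test_header_only_files_pass(self, tmp_path):
        a = make_vcf([], HEADERS, tmp_path / "a.vcf")
        b = make_vcf([], ["##other"], tmp_path / "b.vcf")
        assert compare_vcf_records(a, b).status == "pass"

    def test_record_count_difference_fails(self, tmp_path):
        records = make_random_vcf_records(seed=9, n_records=3)
        a = make_vcf(records, HEADERS, tmp_path / "a.vcf")
        b = make_vcf(records[:-1], HEADERS, tmp_path / "b.vcf")
        assert compare_vcf_records(a, b).status == "fail"

    def test_missing_file_is_error(self, tmp_path):
        a = make_vcf([], HEADERS, tmp_path / "a.vcf")
        assert compare_vcf_records(a, tmp_path / "nope.vcf").status == "error"

    @pytest.mark.parametrize("gz", [False, True])
    def test_header_edits_never_change_status_record_edits_always_do(self, tmp_path, gz):
        """Invariance property over seeded trials: permute/insert/delete header
        lines -> still pass; mutate any single record -> fail."""
        for trial in range(20):
            rng = random.Random(1000 + trial)
            records = make_random_vcf_records(seed=2000 + trial, n_records=rng.randint(1, 8))
            a = make_vcf(records, HEADERS, tmp_path / "a.vcf", gzip=gz)
            headers = HEADERS.copy()
            rng.shuffle(headers)
            if rng.random() < 0.5:
                headers.insert(rng.randrange(len(headers) + 1), f"##extra={trial}")
            if headers and rng.random() < 0.5:
                headers.pop(rng.randrange(len(headers)))
            b = make_vcf(records, headers, tmp_path / "b.vcf", gzip=gz)
            assert compare_vcf_records(a, b).status == "pass"
            mutated = list(records)
            k = rng.randrange(len(mutated))
            mutated[k] = mutated[k] + ";MUT"
            c = make_vcf(mutated, headers, tmp_path / "c.vcf", gzip=gz)
            assert compare_vcf_records(a, c).status == "fail"


class TestEvaluateAssertion:
    def test_checksum_dispatch(self, tmp_path):
        out = tmp_path / "out"
        out.mkdir()
        (out / "r.txt").write_text("payload")
        expect = tmp_path / "e.txt"
        expect.write_text("payload")
        spec = AssertionSpec(actual="*.txt", expect=str(expect))
        assert evaluate_assertion(spec, out).status == "pass"

    def test_unresolvable_pattern_is_error(self, tmp_path):
        out = tmp_path / "out"
        out.mkdir()
        spec = AssertionSpec(actual="*.missing", expect="e")
        assert evaluate_assertion(spec, out).status == "error"

    def test_content_mismatch_never_reported_as_error(self, tmp_path):
        """Error/fail separation for the checksum and script paths."""
        out = tmp_path / "out"
        out.mkdir()
        (out / "r.txt").write_text("AAA")
        expect = tmp_path / "e.txt"
        expect.write_text("BBB")
        checksum = evaluate_assertion(AssertionSpec(actual="r.txt", expect=str(expect)), out)
        assert checksum.status == "fail"
        script = write_fail_script(tmp_path / "cmp.sh")
        spec = AssertionSpec(actual="r.txt", expect=str(expect), method="script", script=str(script))
        assert evaluate_assertion(spec, out).status == "fail"


class TestSnapshots:
    @pytest.fixture
    def recorded(self, tmp_path):
        out = tmp_path / "out"
        out.mkdir()
        (out / "calls.vcf").write_text("rec1\nrec2\n")
        (out / "stats.txt").write_text("n=2\n")
        asserts = [
            AssertionSpec(actual="*.vcf", expect="unused"),
            AssertionSpec(actual="stats.txt", expect="unused"),
        ]
        manifest = record_snapshot("case-x", out, asserts)
        return out, asserts, manifest

    def test_manifest_has_one_entry_per_assertion(self, recorded):
        _, _, manifest = recorded
        assert set(manifest.entries) == {"calls.vcf", "stats.txt"}
        for algorithm, digest in manifest.entries.values():
            assert algorithm == "md5" and len(digest) == 32

    def test_round_trip_all_pass(self, recorded, tmp_path):
        out, _, manifest = recorded
        path = write_snapshot(manifest, snapshot_path(tmp_path, "case-x"))
        results = assert_snapshot(load_snapshot(path), out)
        assert [r.status for r in results] == ["pass", "pass"]

    def test_rerecording_unchanged_outputs_is_identical(self, recorded):
        out, asserts, manifest = recorded
        again = record_snapshot("case-x", out, asserts)
        assert again.entries == manifest.entries

    def test_deleting_one_output_yields_exactly_one_fail(self, recorded):
        out, _, manifest = recorded
        (out / "stats.txt").unlink()
        statuses = [r.status for r in assert_snapshot(manifest, out)]
        assert sorted(statuses) == ["fail", "pass"]

    def test_modifying_one_output_yields_exactly_one_fail(self, recorded):
        out, _, manifest = recorded
        (out / "calls.vcf").write_text("rec1\nrecX\n")
        results = assert_snapshot(manifest, out)
        by_status = {r.status for r in results}
        assert by_status == {"pass", "fail"}
        failing = [r for r in results if r.status == "fail"]
        assert len(failing) == 1 and "calls.vcf" in failing[0].detail

    def test_unreadable_manifest_is_error(self, tmp_path):
        with pytest.raises(InfrastructureError):
            load_snapshot(tmp_path / "missing.snapshot.yaml")

    def test_unresolvable_pattern_aborts_recording(self, tmp_path):
        out = tmp_path / "out"
        out.mkdir()
        with pytest.raises(InfrastructureError):
            record_snapshot("c", out, [AssertionSpec(actual="*.none", expect="u")])
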