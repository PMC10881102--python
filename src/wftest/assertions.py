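"""Output validation: checksums, comparator scripts, VCF record comparison,
and snapshot manifests.

Every assertion produces an :class:`AssertionResult` with a three-way status:

``pass``
    The comparison ran and the contents agree.
``fail``
    The comparison ran and the contents disagree.
``error``
    The comparison could not run: missing file, unresolvable pattern,
    non-executable comparator.  Infrastructure problems are never reported
    as content mismatches.
"""

from __future__ import annotations

import gzip
import hashlib
import os
import subprocess
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import IO

import yaml

from .config_model import AssertionSpec, InfrastructureError

STATUS_PASS = "pass"
STATUS_FAIL = "fail"
STATUS_ERROR = "error"

_CHUNK = 1 << 20
_GZIP_MAGIC = b"\x1f\x8b"


@dataclass
class AssertionResult:
    """Outcome of one assertion: its ordinal within the case, a pass/fail/
    error status, and a human-readable detail line (digests compared, script
    exit code, resolution failure, ...)."""

    index: int
    status: str
    detail: str

    @property
    def passed(self) -> bool:
        return self.status == STATUS_PASS


@dataclass
class SnapshotManifest:
    """Checksums recorded from a reference run of one case.

    ``entries`` maps output-relative paths to ``(algorithm, hex digest)``
    pairs; digests are lowercase hex of the algorithm's standard length
    (md5: 32, sha512: 128).
    """

    case_name: str
    created_at: str = ""
    entries: dict[str, tuple[str, str]] = field(default_factory=dict)


def compute_checksum(path: str | Path, algorithm: str = "md5") -> str:
    """Stream a file through ``hashlib`` and return the lowercase hex digest.

    Memory use is constant in the file size.  A missing or unreadable file
    raises :class:`InfrastructureError` carrying the path.
    """
    if algorithm not in ("md5", "sha512"):
        raise ValueError(f"unsupported checksum algorithm {algorithm!r}")
    digest = hashlib.new(algorithm)
    try:
        with open(path, "rb") as handle:
            while chunk := handle.read(_CHUNK):
                digest.update(chunk)
    except OSError as exc:
        raise InfrastructureError(f"cannot read {path}: {exc}") from exc
    return digest.hexdigest()


def resolve_actual(pattern: str, output_dir: str | Path) -> Path:
    """Find the unique file matching ``pattern`` (glob syntax) under
    ``output_dir``.

    Zero matches and multiple matches are both infrastructure errors —
    ambiguity is never silently resolved.
    """
    root = Path(output_dir)
    if not root.is_dir():
        raise InfrastructureError(f"output directory {root} does not exist")
    matches = sorted(p for p in root.glob(pattern) if p.is_file())
    if not matches:
        raise InfrastructureError(f"no actual file matches {pattern!r} under {root}")
    if len(matches) > 1:
        listed = ", ".join(str(m) for m in matches)
        raise InfrastructureError(f"pattern {pattern!r} is ambiguous: {listed}")
    return matches[0]


def assert_checksum(
    actual: str | Path, expect: str | Path, algorithm: str = "md5", index: int = 0
) -> AssertionResult:
    """Pass iff the two files have equal digests; detail carries both digests."""
    try:
        digest_actual = compute_checksum(actual, algorithm)
        digest_expect = compute_checksum(expect, algorithm)
    except InfrastructureError as exc:
        return AssertionResult(index, STATUS_ERROR, str(exc))
    status = STATUS_PASS if digest_actual == digest_expect else STATUS_FAIL
    return AssertionResult(
        index,
        status,
        f"{algorithm} actual={digest_actual} expect={digest_expect}",
    )


def assert_script(
    script: str | Path, actual: str | Path, expect: str | Path, index: int = 0
) -> AssertionResult:
    """Run a custom comparator: ``script actual expect``; exit 0 is a pass,
    any nonzero exit is a fail.  The script's stdout/stderr are preserved in
    the detail."""
    script = Path(script)
    if not script.is_file() or not os.access(script, os.X_OK):
        return AssertionResult(
            index, STATUS_ERROR, f"comparator script {script} missing or not executable"
        )
    for path in (actual, expect):
        if not Path(path).is_file():
            return AssertionResult(index, STATUS_ERROR, f"input file {path} does not exist")
    proc = subprocess.run(
        [str(script), str(actual), str(expect)],
        capture_output=True,
        text=True,
    )
    status = STATUS_PASS if proc.returncode == 0 else STATUS_FAIL
    output = (proc.stdout + proc.stderr).strip()
    detail = f"comparator exit {proc.returncode}"
    if output:
        detail += f": {output}"
    return AssertionResult(index, status, detail)


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    """Open plain or gzip-compressed text, sniffing the gzip magic bytes —
    extensions lie often enough in pipeline outputs."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _vcf_records(path: str | Path) -> list[str]:
    try:
        with _open_maybe_gzip(path) as handle:
            return [
                line.rstrip("\n").rstrip("\r")
                for line in handle
                if not line.startswith("#")
            ]
    except OSError as exc:
        raise InfrastructureError(f"cannot read VCF {path}: {exc}") from exc


def compare_vcf_records(
    file_a: str | Path, file_b: str | Path, index: int = 0
) -> AssertionResult:
    """Header-insensitive VCF comparison.

    Every line starting with ``#`` — the ``##`` meta lines and the
    ``#CHROM`` column line — is discarded; the remaining record lines are
    compared as ordered sequences of strings.  Valid VCFs are
    coordinate-sorted, so order-sensitive comparison is deterministic
    without any normalization.  Accepts plain or gzip-compressed input.
    """
    try:
        records_a = _vcf_records(file_a)
        records_b = _vcf_records(file_b)
    except InfrastructureError as exc:
        return AssertionResult(index, STATUS_ERROR, str(exc))
    if records_a == records_b:
        return AssertionResult(
            index, STATUS_PASS, f"{len(records_a)} records identical (headers ignored)"
        )
    for i, (rec_a, rec_b) in enumerate(zip(records_a, records_b)):
        if rec_a != rec_b:
            return AssertionResult(
                index, STATUS_FAIL, f"records differ first at index {i}"
            )
    return AssertionResult(
        index,
        STATUS_FAIL,
        f"record counts differ: {len(records_a)} vs {len(records_b)}",
    )


def evaluate_assertion(
    spec: AssertionSpec, output_dir: str | Path, index: int = 0
) -> AssertionResult:
    """Resolve the actual file for one :class:`AssertionSpec` and dispatch on
    its method."""
    try:
        actual = resolve_actual(spec.actual, output_dir)
    except InfrastructureError as exc:
        return AssertionResult(index, STATUS_ERROR, str(exc))
    if spec.method == "checksum":
        return assert_checksum(actual, spec.expect, spec.algorithm, index=index)
    if spec.method == "script":
        assert spec.script is not None  # guaranteed by suite validation
        return assert_script(spec.script, actual, spec.expect, index=index)
    return AssertionResult(index, STATUS_ERROR, f"unsupported method {spec.method!r}")


# -- snapshots ---------------------------------------------------------------


def record_snapshot(
    case_name: str,
    output_dir: str | Path,
    asserts: list[AssertionSpec],
    algorithm: str = "md5",
) -> SnapshotManifest:
    """Record a reference run: one digest per resolved actual file.

    Run this after a case completes on a trusted build; later runs are then
    validated against the manifest with :func:`assert_snapshot` instead of
    hand-curated expected files.  An unresolvable pattern raises
    :class:`InfrastructureError`.
    """
    root = Path(output_dir)
    entries: dict[str, tuple[str, str]] = {}
    for spec in asserts:
        actual = resolve_actual(spec.actual, root)
        rel = actual.relative_to(root).as_posix()
        entries[rel] = (algorithm, compute_checksum(actual, algorithm))
    return SnapshotManifest(
        case_name=case_name,
        created_at=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        entries=entries,
    )


def snapshot_path(test_dir: str | Path, case_name: str) -> Path:
    """Conventional manifest location: ``<test_dir>/<case>.snapshot.yaml``."""
    return Path(test_dir) / f"{case_name}.snapshot.yaml"


def write_snapshot(manifest: SnapshotManifest, path: str | Path) -> Path:
    doc = {
        "case_name": manifest.case_name,
        "created_at": manifest.created_at,
        "entries": {
            rel: {"algorithm": alg, "digest": digest}
            for rel, (alg, digest) in manifest.entries.items()
        },
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")
    return path


def load_snapshot(path: str | Path) -> SnapshotManifest:
    try:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except (OSError, yaml.YAMLError) as exc:
        raise InfrastructureError(f"cannot read snapshot manifest {path}: {exc}") from exc
    if not isinstance(doc, dict) or "entries" not in doc:
        raise InfrastructureError(f"snapshot manifest {path} is malformed")
    entries = {
        rel: (entry["algorithm"], entry["digest"])
        for rel, entry in doc["entries"].items()
    }
    return SnapshotManifest(
        case_name=doc.get("case_name", ""),
        created_at=doc.get("created_at", ""),
        entries=entries,
    )


def assert_snapshot(
    manifest: SnapshotManifest, output_dir: str | Path
) -> list[AssertionResult]:
    """Compare current outputs against a recorded manifest, one result per
    entry in manifest order.

    A file that has vanished from the output directory is a ``fail`` (the
    run regressed relative to the reference), not an infrastructure error.
    Files present in the output directory but absent from the manifest are
    ignored.
    """
    root = Path(output_dir)
    results: list[AssertionResult] = []
    for index, (rel, (algorithm, recorded)) in enumerate(manifest.entries.items()):
        current_path = root / rel
        if not current_path.is_file():
            results.append(
                AssertionResult(index, STATUS_FAIL, f"{rel}: missing from output")
            )
            continue
        current = compute_checksum(current_path, algorithm)
        if current == recorded:
            results.append(
                AssertionResult(index, STATUS_PASS, f"{rel}: {algorithm} {current}")
            )
        else:
            results.append(
                AssertionResult(
                    index,
                    STATUS_FAIL,
                    f"{rel}: {algorithm} recorded={recorded} current={current}",
                )
            )
    return results
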