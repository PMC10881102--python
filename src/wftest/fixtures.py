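"""Generated test doubles: a stub workflow engine, synthetic VCFs, and
seeded random files.

Everything here is created at run time so the harness's own test suite
needs no engine installation, no JVM, and no downloaded datasets.  The stub
engine is a plain Python script that speaks exactly the command-line
surface the runner emits (``-c``, ``run``, ``-profile``, ``-params-file``,
``--<param> value``, ``-w``), writes declared output files into the
directory named by the ``--<param>`` argument, optionally records its argv
for command-construction tests, and exits with a configured status.
"""

from __future__ import annotations

import gzip as gzip_mod
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

ARGV_CAPTURE_NAME = ".wftest_argv"
WORK_MARKER_NAME = "engine-scratch.txt"

#: Standard VCF column header line.
VCF_COLUMNS = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"


@dataclass
class StubBehavior:
    """Configured behaviour of one stub engine.

    ``outputs`` maps output-relative paths to literal file content, written
    under the output directory only when ``exit_code`` is 0 (a failed run
    produces no final outputs, like a real engine).  With ``echo_args`` the
    stub writes its argv, one token per line, to ``.wftest_argv`` in the
    output directory regardless of exit code.
    """

    exit_code: int = 0
    outputs: dict[str, str] = field(default_factory=dict)
    echo_args: bool = False

    def __post_init__(self) -> None:
        for rel in self.outputs:
            p = Path(rel)
            if p.is_absolute() or ".." in p.parts:
                raise ValueError(f"output path {rel!r} must be relative without traversal")


_STUB_TEMPLATE = '''#!/usr/bin/env python3
"""Stub workflow engine for harness testing (generated)."""
import json, os, sys

BEHAVIOR = json.loads({behavior_json!r})
ARGV_CAPTURE_NAME = {capture!r}
WORK_MARKER_NAME = {marker!r}

args = sys.argv[1:]
output_dir = None
work_dir = None
i = 0
while i < len(args):
    tok = args[i]
    if tok in ("-c", "-profile", "-params-file"):
        i += 2
    elif tok == "-w":
        work_dir = args[i + 1]
        i += 2
    elif tok == "run":
        i += 2  # consumes the script/repo reference too
    elif tok.startswith("--"):
        if output_dir is None:
            output_dir = args[i + 1]
        i += 2
    else:
        sys.stderr.write("stub engine: unexpected token %r\\n" % tok)
        sys.exit(64)

if work_dir:
    os.makedirs(work_dir, exist_ok=True)
    with open(os.path.join(work_dir, WORK_MARKER_NAME), "w") as fh:
        fh.write("intermediate scratch\\n")

if output_dir:
    os.makedirs(output_dir, exist_ok=True)
    if BEHAVIOR.get("echo_args"):
        with open(os.path.join(output_dir, ARGV_CAPTURE_NAME), "w") as fh:
            fh.write("\\n".join(args) + "\\n")
    if BEHAVIOR.get("exit_code", 0) == 0:
        for rel, content in BEHAVIOR.get("outputs", {{}}).items():
            dest = os.path.join(output_dir, rel)
            parent = os.path.dirname(dest)
            if parent:
                os.makedirs(parent, exist_ok=True)
            with open(dest, "w") as fh:
                fh.write(content)

sys.exit(BEHAVIOR.get("exit_code", 0))
'''


def make_stub_engine(behavior: StubBehavior, dest: str | Path) -> Path:
    """Write an executable stub engine into ``dest`` and return its path.

    The stub is a portable interpreted script — no compilation, no
    toolchain.  It rejects any token it cannot classify with exit code 64,
    which makes it a real check on command construction, not just a sink.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    behavior_json = json.dumps(
        {
            "exit_code": behavior.exit_code,
            "outputs": behavior.outputs,
            "echo_args": behavior.echo_args,
        }
    )
    script = dest / "stub-engine"
    script.write_text(
        _STUB_TEMPLATE.format(
            behavior_json=behavior_json,
            capture=ARGV_CAPTURE_NAME,
            marker=WORK_MARKER_NAME,
        ),
        encoding="utf-8",
    )
    script.chmod(0o755)
    return script


def read_argv_capture(output_dir: str | Path) -> list[str]:
    """Tokens the stub engine received, from its capture file."""
    text = (Path(output_dir) / ARGV_CAPTURE_NAME).read_text(encoding="utf-8")
    return text.rstrip("\n").split("\n") if text.strip() else []


def make_vcf(
    records: list[str],
    header_lines: list[str],
    dest: str | Path,
    gzip: bool = False,
) -> Path:
    """Write a small VCF: meta header lines (``##``-prefixed if not
    already), the ``#CHROM`` column line, then the record lines; optionally
    gzip-compressed."""
    lines = []
    for header in header_lines:
        lines.append(header if header.startswith("#") else "##" + header)
    lines.append(VCF_COLUMNS)
    lines.extend(records)
    text = "\n".join(lines) + "\n"
    dest = Path(dest)
    if gzip:
        with gzip_mod.open(dest, "wt", encoding="utf-8") as fh:
            fh.write(text)
    else:
        dest.write_text(text, encoding="utf-8")
    return dest


def make_random_vcf_records(seed: int, n_records: int) -> list[str]:
    """Deterministic toy variant records: sorted positions on one contig,
    random SNV alleles."""
    rng = random.Random(seed)
    positions = sorted(rng.sample(range(1, 10 * max(n_records, 1) + 2), n_records))
    bases = "ACGT"
    records = []
    for pos in positions:
        ref = rng.choice(bases)
        alt = rng.choice([b for b in bases if b != ref])
        qual = round(rng.uniform(10, 99), 1)
        records.append(f"chr21\t{pos}\t.\t{ref}\t{alt}\t{qual}\tPASS\t.")
    return records


def make_random_file(seed: int, size: int, dest: str | Path) -> Path:
    """Write ``size`` deterministic pseudo-random bytes; the same seed and
    size always reproduce the identical file."""
    dest = Path(dest)
    dest.write_bytes(random.Random(seed).randbytes(size))
    return dest
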