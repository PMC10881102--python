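"""Engine command assembly, case execution, and post-run cleanup.

The harness never re-implements workflow-engine semantics: it builds the
engine's command line from the resolved settings and the case definition,
runs it as a subprocess with stdout/stderr captured to per-case log files,
and treats a nonzero engine exit as the case's (implicit) first failed
assertion — completion is a prerequisite for every other check.
"""

from __future__ import annotations

import logging
import os
import shutil
import subprocess
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .assertions import AssertionResult, evaluate_assertion
from .config_model import (
    EffectiveSettings,
    EnvContext,
    GlobalSettings,
    InfrastructureError,
    TestCase,
    resolve_effective_settings,
)

LOG = logging.getLogger("wftest")

DEFAULT_ENGINE = "nextflow"


@dataclass
class RunRecord:
    """One engine invocation: the exact command, its exit status (recorded
    even on failure), the captured log paths and the work directory."""

    case_name: str
    command: list[str]
    exit_status: int
    stdout_log: Path
    stderr_log: Path
    work_dir: Path
    started: datetime
    ended: datetime


@dataclass
class CaseResult:
    """Aggregate verdict for one case.

    ``passed`` holds iff the engine exited 0 and every assertion passed.
    ``record`` and ``settings`` carry the execution context onward for
    cleanup and reporting.
    """

    case_name: str
    engine_exit: int
    assertion_results: list[AssertionResult] = field(default_factory=list)
    passed: bool = False
    record: RunRecord | None = None
    settings: EffectiveSettings | None = None


def build_engine_command(
    settings: EffectiveSettings,
    case: TestCase,
    engine_binary: str = DEFAULT_ENGINE,
) -> list[str]:
    """Assemble the engine command as a deterministic token list.

    Order: engine binary; ``-c`` per config file — the suite-wide config
    first so case configs can override it (the engine lets later configs
    win); ``run``; the script path or ``organization/repository`` reference
    verbatim; ``-profile p1,p2,...`` iff profiles are declared;
    ``-params-file`` iff set; the pipeline's own output-directory parameter
    as ``--<name> <output_dir>``; and ``-w <temp_dir>``.

    Pure construction: no filesystem access, no side effects.
    """
    command = [engine_binary]
    if settings.nf_config:
        command += ["-c", settings.nf_config]
    for config in case.nf_configs:
        command += ["-c", config]
    command += ["run", case.nf_script]
    if case.profiles:
        command += ["-profile", ",".join(case.profiles)]
    if case.params_file:
        command += ["-params-file", case.params_file]
    command += [f"--{case.output_directory_param_name}", settings.output_dir]
    command += ["-w", settings.temp_dir]
    return command


def _resolve_engine(engine_binary: str) -> str:
    """Accept either a path to an executable or a name on PATH."""
    candidate = Path(engine_binary)
    if candidate.is_file() and os.access(candidate, os.X_OK):
        return str(candidate)
    found = shutil.which(engine_binary)
    if found:
        return found
    raise InfrastructureError(f"engine binary {engine_binary!r} not found or not executable")


def execute_case(
    settings: EffectiveSettings,
    case: TestCase,
    engine_binary: str = DEFAULT_ENGINE,
    log_dir: str | Path = ".",
) -> RunRecord:
    """Run the engine for one case.

    Creates the output and work directories if absent, redirects engine
    stdout/stderr to ``<case>.stdout.log`` / ``<case>.stderr.log`` under
    ``log_dir``, and returns a complete :class:`RunRecord` whatever the
    engine's exit status — a failing pipeline is a test outcome, not an
    exception.  Only a missing engine binary or an uncreatable directory
    raises :class:`InfrastructureError`.
    """
    engine = _resolve_engine(engine_binary)
    command = [engine] + build_engine_command(settings, case)[1:]
    log_dir = Path(log_dir)
    try:
        Path(settings.output_dir).mkdir(parents=True, exist_ok=True)
        Path(settings.temp_dir).mkdir(parents=True, exist_ok=True)
        log_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InfrastructureError(f"cannot create run directories: {exc}") from exc
    stdout_log = log_dir / f"{case.name}.stdout.log"
    stderr_log = log_dir / f"{case.name}.stderr.log"
    started = datetime.now(timezone.utc)
    with open(stdout_log, "w") as out, open(stderr_log, "w") as err:
        proc = subprocess.run(command, stdout=out, stderr=err)
    ended = datetime.now(timezone.utc)
    LOG.debug("case %r: %s exited %d", case.name, " ".join(command), proc.returncode)
    return RunRecord(
        case_name=case.name,
        command=command,
        exit_status=proc.returncode,
        stdout_log=stdout_log,
        stderr_log=stderr_log,
        work_dir=Path(settings.temp_dir),
        started=started,
        ended=ended,
    )


def run_case(
    global_settings: GlobalSettings,
    case: TestCase,
    env: EnvContext,
    engine_binary: str = DEFAULT_ENGINE,
    log_dir: str | Path = ".",
) -> CaseResult:
    """Resolve settings, execute the engine, then evaluate the case's
    assertions.

    If the engine exits nonzero the case fails immediately with zero
    assertion results: completion is the implicit first assertion, and a
    case with an empty ``asserts`` list is exactly a completion-only test.
    On success every assertion is evaluated — no short-circuit on the first
    failure, so the report is always complete.  An infrastructure error in
    one assertion marks that assertion ``error`` and fails the case without
    stopping the others.
    """
    settings = resolve_effective_settings(global_settings, case, env)
    record = execute_case(settings, case, engine_binary, log_dir)
    LOG.info("case %r: engine exit %d", case.name, record.exit_status)
    if record.exit_status != 0:
        return CaseResult(
            case_name=case.name,
            engine_exit=record.exit_status,
            assertion_results=[],
            passed=False,
            record=record,
            settings=settings,
        )
    results = [
        evaluate_assertion(spec, settings.output_dir, index=i)
        for i, spec in enumerate(case.asserts)
    ]
    for result in results:
        LOG.info(
            "case %r: assertion %d %s (%s)",
            case.name,
            result.index,
            result.status,
            result.detail,
        )
    return CaseResult(
        case_name=case.name,
        engine_exit=0,
        assertion_results=results,
        passed=all(r.passed for r in results),
        record=record,
        settings=settings,
    )


def cleanup_case(
    result: CaseResult, record: RunRecord, settings: EffectiveSettings
) -> list[Path]:
    """Apply the cleanup flags after a case finishes.

    Only a *passing* case is cleaned: ``remove_temp`` deletes the engine
    work directory, ``clean_logs`` deletes the captured engine log files.
    A failed case retains everything for debugging regardless of the flags.
    Expected files, the test definitions and anything outside the work
    directory and log locations are never touched; a deletion failure is a
    warning, never a case failure.
    """
    removed: list[Path] = []
    if not result.passed:
        return removed
    if settings.remove_temp and record.work_dir.is_dir():
        try:
            shutil.rmtree(record.work_dir)
            removed.append(record.work_dir)
        except OSError as exc:
            LOG.warning("could not remove work dir %s: %s", record.work_dir, exc)
    if settings.clean_logs:
        for log_path in (record.stdout_log, record.stderr_log):
            if log_path.is_file():
                try:
                    log_path.unlink()
                    removed.append(log_path)
                except OSError as exc:
                    LOG.warning("could not remove log %s: %s", log_path, exc)
    return removed
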