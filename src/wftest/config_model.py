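"""Test-definition data model: YAML schema, validation, and the settings hierarchy.

A test suite is one YAML document with two top-level keys:

``global``
    Suite-wide defaults (work directory, a shared engine config file,
    cleanup flags).
``cases``
    An ordered list of named test cases.  Each case names the workflow
    script (or ``organization/repository`` reference) to run, its engine
    config files, profiles and params-file, and the assertions applied to
    its outputs.  A case may restate any ``global`` field to override it.

Per-developer paths come from environment variables so test definitions can
be committed unchanged: ``WFTEST_OUTPUT`` (output base directory),
``WFTEST_TEMP`` (engine work directory) and ``WFTEST_LOG_LEVEL``.

Settings precedence, highest first: environment variable, case-level
override, global block, built-in default.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, ClassVar

import yaml

LOG = logging.getLogger("wftest")

# -- schema constants --------------------------------------------------------

ENV_OUTPUT = "WFTEST_OUTPUT"
ENV_TEMP = "WFTEST_TEMP"
ENV_LOG_LEVEL = "WFTEST_LOG_LEVEL"

DEFAULT_TEMP_DIR = "wftest-work"
DEFAULT_OUTPUT_BASE = "wftest-output"
DEFAULT_OUTPUT_PARAM = "output_dir"

CHECKSUM_ALGORITHMS = ("md5", "sha512")
ASSERTION_METHODS = ("checksum", "script")
LOG_LEVELS = ("debug", "info", "warning", "error")

SCRIPT_EXTENSIONS = (".nf",)

_GLOBAL_FIELDS = ("temp_dir", "nf_config", "remove_temp", "clean_logs")
_CASE_FIELDS = (
    "name",
    "message",
    "enabled",
    "nf_script",
    "nf_configs",
    "profiles",
    "params_file",
    "output_directory_param_name",
    "asserts",
) + _GLOBAL_FIELDS
_ASSERT_FIELDS = ("actual", "expect", "method", "algorithm", "script")


# -- errors ------------------------------------------------------------------


class WftestError(Exception):
    """Base class for all suite-level failures."""


class TestFileParseError(WftestError):
    """The YAML document itself is malformed."""

    __test__ = False  # keep pytest from collecting the Test- prefix


class SuiteValidationError(WftestError):
    """The document parsed but violates the schema invariants."""

    def __init__(self, findings: list["ValidationFinding"]):
        self.findings = findings
        super().__init__("; ".join(str(f) for f in findings))


class UnknownCaseError(WftestError):
    """A requested case name matches nothing in the suite."""

    def __init__(self, unknown: list[str]):
        self.unknown = unknown
        super().__init__(f"unknown test case name(s): {', '.join(unknown)}")


class InfrastructureError(WftestError):
    """A failure of the harness environment (missing file, bad binary, I/O),
    as opposed to a failed comparison."""


# -- domain types ------------------------------------------------------------


@dataclass
class GlobalSettings:
    """Suite-wide defaults.  ``None`` means "unset here": the value falls
    through to the next level of the hierarchy at resolution time."""

    temp_dir: str | None = None
    nf_config: str | None = None
    remove_temp: bool | None = None
    clean_logs: bool | None = None

    def set_fields(self) -> dict[str, Any]:
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) is not None
        }


@dataclass
class AssertionSpec:
    """One output validation.

    ``actual`` is a glob pattern resolved under the case's output directory;
    ``expect`` is the expected artifact on disk.  ``method`` is either
    ``checksum`` (digest equality, ``algorithm`` md5 or sha512) or ``script``
    (an executable comparator invoked as ``script actual expect``, exit 0 =
    pass).
    """

    actual: str
    expect: str
    method: str = "checksum"
    algorithm: str = "md5"
    script: str | None = None


@dataclass
class TestCase:
    """One named workflow execution plus the assertions validating it.

    ``nf_script`` is either a local script path or a remote
    ``organization/repository`` reference passed verbatim to the engine.
    An empty ``asserts`` list is legal and means completion-only testing.
    ``overrides`` restates any :class:`GlobalSettings` field for this case.
    """

    __test__: ClassVar[bool] = False  # keep pytest from collecting the Test- prefix

    name: str
    nf_script: str
    message: str = ""
    enabled: bool = True
    nf_configs: list[str] = field(default_factory=list)
    profiles: list[str] = field(default_factory=list)
    params_file: str | None = None
    output_directory_param_name: str = DEFAULT_OUTPUT_PARAM
    asserts: list[AssertionSpec] = field(default_factory=list)
    overrides: GlobalSettings = field(default_factory=GlobalSettings)


@dataclass
class EnvContext:
    """Per-developer settings read from the process environment.

    All fields optional; an empty context leaves file-based settings
    untouched.
    """

    output_dir: str | None = None
    temp_dir: str | None = None
    log_level: str | None = None

    @classmethod
    def from_environ(cls, environ: dict[str, str] | None = None) -> "EnvContext":
        env = os.environ if environ is None else environ
        return cls(
            output_dir=env.get(ENV_OUTPUT) or None,
            temp_dir=env.get(ENV_TEMP) or None,
            log_level=env.get(ENV_LOG_LEVEL) or None,
        )


@dataclass
class EffectiveSettings:
    """Fully resolved values one case runs with.  Every field is concrete;
    ``nf_config`` may be None, meaning "no suite-wide engine config"."""

    temp_dir: str
    nf_config: str | None
    remove_temp: bool
    clean_logs: bool
    output_dir: str


@dataclass
class ValidationFinding:
    """One schema violation: the case (or 'global'), field and broken rule."""

    case_name: str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - trivial formatting
        return f"[{self.case_name}] {self.field}: {self.message}"


# -- parsing -----------------------------------------------------------------


def _parse_assertion(raw: Any, case_name: str, index: int) -> AssertionSpec:
    if not isinstance(raw, dict):
        raise SuiteValidationError(
            [ValidationFinding(case_name, f"asserts[{index}]", "must be a mapping")]
        )
    for key in raw:
        if key not in _ASSERT_FIELDS:
            LOG.warning("case %r assert %d: unrecognized key %r ignored", case_name, index, key)
    return AssertionSpec(
        actual=raw.get("actual", ""),
        expect=raw.get("expect", ""),
        method=raw.get("method", "checksum"),
        algorithm=raw.get("algorithm", "md5"),
        script=raw.get("script"),
    )


def _parse_global(raw: Any) -> GlobalSettings:
    if raw is None:
        return GlobalSettings()
    if not isinstance(raw, dict):
        raise SuiteValidationError(
            [ValidationFinding("global", "global", "global block must be a mapping")]
        )
    for key in raw:
        if key not in _GLOBAL_FIELDS:
            LOG.warning("global block: unrecognized key %r ignored", key)
    return GlobalSettings(
        temp_dir=raw.get("temp_dir"),
        nf_config=raw.get("nf_config"),
        remove_temp=raw.get("remove_temp"),
        clean_logs=raw.get("clean_logs"),
    )


def _parse_case(raw: Any, position: int) -> TestCase:
    label = f"case #{position + 1}"
    if not isinstance(raw, dict):
        raise SuiteValidationError([ValidationFinding(label, "case", "must be a mapping")])
    name = raw.get("name")
    if not isinstance(name, str) or not name:
        raise SuiteValidationError(
            [ValidationFinding(label, "name", "required field missing or empty")]
        )
    nf_script = raw.get("nf_script")
    if not isinstance(nf_script, str) or not nf_script:
        raise SuiteValidationError(
            [ValidationFinding(name, "nf_script", "required field missing or empty")]
        )
    for key in raw:
        if key not in _CASE_FIELDS:
            LOG.warning("case %r: unrecognized key %r ignored", name, key)
    asserts = [
        _parse_assertion(a, name, i) for i, a in enumerate(raw.get("asserts") or [])
    ]
    overrides = GlobalSettings(
        temp_dir=raw.get("temp_dir"),
        nf_config=raw.get("nf_config"),
        remove_temp=raw.get("remove_temp"),
        clean_logs=raw.get("clean_logs"),
    )
    return TestCase(
        name=name,
        nf_script=nf_script,
        message=raw.get("message") or "",
        enabled=True if raw.get("enabled") is None else bool(raw.get("enabled")),
        nf_configs=list(raw.get("nf_configs") or []),
        profiles=list(raw.get("profiles") or []),
        params_file=raw.get("params_file"),
        output_directory_param_name=raw.get("output_directory_param_name")
        or DEFAULT_OUTPUT_PARAM,
        asserts=asserts,
        overrides=overrides,
    )


def load_test_file(path: str | Path) -> tuple[GlobalSettings, list[TestCase]]:
    """Parse and validate a YAML test-definition file.

    Returns the global settings and the cases in file order.  Unrecognized
    top-level keys are logged as warnings, not errors.

    Raises
    ------
    TestFileParseError
        Malformed YAML; the message names the offending line.
    SuiteValidationError
        Duplicate case names, missing required fields, or any schema
        invariant violation found by :func:`validate_suite`.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise TestFileParseError(f"{path}: malformed YAML{where}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise TestFileParseError(f"{path}: top level must be a mapping")
    for key in data:
        if key not in ("global", "cases"):
            LOG.warning("%s: unrecognized top-level key %r ignored", path, key)
    global_settings = _parse_global(data.get("global"))
    raw_cases = data.get("cases") or []
    if not isinstance(raw_cases, list):
        raise SuiteValidationError(
            [ValidationFinding("global", "cases", "cases must be a list")]
        )
    cases = [_parse_case(raw, i) for i, raw in enumerate(raw_cases)]
    findings = validate_suite(global_settings, cases)
    if findings:
        raise SuiteValidationError(findings)
    return global_settings, cases


def serialize_suite(global_settings: GlobalSettings, cases: list[TestCase]) -> str:
    """Render a suite back to YAML.  ``load_test_file`` on the result yields a
    structurally equal suite (round-trip property)."""
    doc: dict[str, Any] = {}
    gset = global_settings.set_fields()
    if gset:
        doc["global"] = gset
    out_cases = []
    for case in cases:
        raw: dict[str, Any] = {
            "name": case.name,
            "nf_script": case.nf_script,
            "message": case.message,
            "enabled": case.enabled,
            "nf_configs": list(case.nf_configs),
            "profiles": list(case.profiles),
            "params_file": case.params_file,
            "output_directory_param_name": case.output_directory_param_name,
            "asserts": [
                {
                    "actual": a.actual,
                    "expect": a.expect,
                    "method": a.method,
                    "algorithm": a.algorithm,
                    "script": a.script,
                }
                for a in case.asserts
            ],
        }
        raw.update(case.overrides.set_fields())
        out_cases.append(raw)
    doc["cases"] = out_cases
    return yaml.safe_dump(doc, sort_keys=False)


# -- validation --------------------------------------------------------------


def validate_suite(
    global_settings: GlobalSettings, cases: list[TestCase]
) -> list[ValidationFinding]:
    """Check every schema invariant; returns findings as data, empty iff valid."""
    findings: list[ValidationFinding] = []

    def _check_override_types(owner: str, settings: GlobalSettings) -> None:
        for fname, expected in (
            ("temp_dir", str),
            ("nf_config", str),
            ("remove_temp", bool),
            ("clean_logs", bool),
        ):
            value = getattr(settings, fname)
            if value is not None and not isinstance(value, expected):
                findings.append(
                    ValidationFinding(
                        owner, fname, f"must be {expected.__name__}, got {type(value).__name__}"
                    )
                )

    if global_settings.temp_dir is not None and not global_settings.temp_dir:
        findings.append(ValidationFinding("global", "temp_dir", "must be non-empty when set"))
    _check_override_types("global", global_settings)

    seen: set[str] = set()
    for case in cases:
        if not case.name:
            findings.append(ValidationFinding("<unnamed>", "name", "must be non-empty"))
        elif case.name in seen:
            findings.append(
                ValidationFinding(case.name, "name", "duplicate case name")
            )
        else:
            seen.add(case.name)
        if not case.nf_script:
            findings.append(ValidationFinding(case.name, "nf_script", "must be non-empty"))
        _check_override_types(case.name, case.overrides)
        for i, spec in enumerate(case.asserts):
            where = f"asserts[{i}]"
            if not spec.actual:
                findings.append(ValidationFinding(case.name, where, "actual must be non-empty"))
            if not spec.expect:
                findings.append(ValidationFinding(case.name, where, "expect must be non-empty"))
            if spec.method not in ASSERTION_METHODS:
                findings.append(
                    ValidationFinding(
                        case.name, where, f"unsupported method {spec.method!r}"
                    )
                )
            if spec.method == "checksum":
                if spec.algorithm not in CHECKSUM_ALGORITHMS:
                    findings.append(
                        ValidationFinding(
                            case.name, where, f"unsupported algorithm {spec.algorithm!r}"
                        )
                    )
                if spec.script is not None:
                    findings.append(
                        ValidationFinding(
                            case.name, where, "script must be unset for method=checksum"
                        )
                    )
            if spec.method == "script" and not spec.script:
                findings.append(
                    ValidationFinding(
                        case.name, where, "script is required for method=script"
                    )
                )
    return findings


# -- resolution & selection --------------------------------------------------


def _first_set(*values: Any, default: Any) -> Any:
    for value in values:
        if value is not None:
            return value
    return default


def resolve_effective_settings(
    global_settings: GlobalSettings, case: TestCase, env: EnvContext
) -> EffectiveSettings:
    """Merge the three-level hierarchy into concrete per-case settings.

    Precedence per field, highest first: environment > case override >
    global > built-in default.  Resolution is total: every field comes out
    concrete.  The output directory is ``<base>/<case name>`` where the base
    is the ``WFTEST_OUTPUT`` environment value or a built-in default; the
    per-case subdirectory keeps concurrent cases from clobbering each other
    and is what assertion patterns resolve against.
    """
    ov = case.overrides
    output_base = _first_set(env.output_dir, default=DEFAULT_OUTPUT_BASE)
    return EffectiveSettings(
        temp_dir=_first_set(
            env.temp_dir, ov.temp_dir, global_settings.temp_dir, default=DEFAULT_TEMP_DIR
        ),
        nf_config=_first_set(ov.nf_config, global_settings.nf_config, default=None),
        remove_temp=_first_set(
            ov.remove_temp, global_settings.remove_temp, default=False
        ),
        clean_logs=_first_set(ov.clean_logs, global_settings.clean_logs, default=False),
        output_dir=os.path.join(output_base, case.name),
    )


def select_cases(cases: list[TestCase], requested_names: list[str]) -> list[TestCase]:
    """Pick the cases to execute.

    With no requested names, returns the enabled cases in file order.  With
    names, returns exactly the named cases (exact, case-sensitive match) in
    file order regardless of their ``enabled`` flag; duplicates in the
    request are ignored.

    Raises :class:`UnknownCaseError` listing any requested name that matches
    no case — the suite does not run at all in that situation.
    """
    if not requested_names:
        return [c for c in cases if c.enabled]
    known = {c.name for c in cases}
    requested = list(dict.fromkeys(requested_names))  # de-dup, keep order
    unknown = [n for n in requested if n not in known]
    if unknown:
        raise UnknownCaseError(unknown)
    wanted = set(requested)
    return [c for c in cases if c.name in wanted]


def is_remote_script(reference: str) -> bool:
    """True when a workflow reference looks like ``organization/repository``
    rather than a local path: exactly one slash, no ``./`` or ``/`` prefix,
    and no workflow-script extension."""
    return (
        reference.count("/") == 1
        and not reference.startswith(("./", "/"))
        and not reference.endswith(SCRIPT_EXTENSIONS)
    )
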