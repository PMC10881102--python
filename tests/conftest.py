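"""Shared fixtures: stub engines, suite files, and an isolated cwd."""

from __future__ import annotations

from pathlib import Path

import pytest
import yaml

from wftest import StubBehavior, make_stub_engine


@pytest.fixture
def in_tmp(tmp_path, monkeypatch):
    """Run the test with cwd inside a fresh tmp dir so relative default
    paths (output/work dirs) stay isolated."""
    monkeypatch.chdir(tmp_path)
    monkeypatch.delenv("WFTEST_OUTPUT", raising=False)
    monkeypatch.delenv("WFTEST_TEMP", raising=False)
    monkeypatch.delenv("WFTEST_LOG_LEVEL", raising=False)
    return tmp_path


@pytest.fixture
def stub_factory(tmp_path):
    """Factory producing stub engines with a given behaviour; each stub
    lands in its own subdirectory."""
    counter = {"n": 0}

    def make(exit_code=0, outputs=None, echo_args=False):
        counter["n"] += 1
        behavior = StubBehavior(
            exit_code=exit_code, outputs=outputs or {}, echo_args=echo_args
        )
        return make_stub_engine(behavior, tmp_path / f"stub{counter['n']}")

    return make


@pytest.fixture
def write_suite(tmp_path):
    """Write a test-definition YAML from a plain mapping and return its path."""
    counter = {"n": 0}

    def write(doc: dict, name: str | None = None) -> Path:
        counter["n"] += 1
        path = tmp_path / (name or f"suite{counter['n']}.yaml")
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
        return path

    return write


def completion_case(name: str, enabled: bool = True, **extra) -> dict:
    """Minimal completion-only case mapping for suite files."""
    case = {"name": name, "nf_script": "./main.nf", "enabled": enabled}
    case.update(extra)
    return case
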