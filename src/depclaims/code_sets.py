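"""Named ICD-10 / ATC code sets with prefix-matching semantics.

Every selection rule in the pipeline is defined by a :class:`CodeSet`: a code
matches when, after normalisation (uppercase, dots stripped, so ``F32.1`` ≡
``F321``), it starts with at least one include prefix and with no exclude
prefix.  Prefix semantics mirror the ICD-10 / ATC hierarchies: the
three-character block ``F32`` covers every ``F32.x`` subcode.

The default registry ships as an editable YAML file next to this module
(``code_registry.yaml``) so drug lists can be swapped without code changes.
It defines:

* ``DEPRESSION`` — ICD-10 F32–F39 (F35–F38 are unused blocks in ICD-10 but
  are kept verbatim; matching them is harmless).
* ``BIPOLAR_DX`` — ICD-10 F30, F31 (manic episode / bipolar disorder).
* ``ANTIDEPRESSANT`` — ATC N06A except oxitriptan (N06AX01).
* ``BIPOLAR_DRUG`` — mood stabilisers treated as specific bipolar treatment:
  lithium (N05AN01), valproic acid / divalproex (N03AG01), valpromide
  (N03AG02).
* ``ANXIOLYTIC`` (N05B), ``HYPNOTIC`` (N05C), ``NEUROLEPTIC`` (N05A minus
  lithium N05AN) — used only for cohort profiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["CodeSet", "code_matches", "normalise_code", "default_registry", "load_registry"]


def normalise_code(code: str) -> str:
    """Uppercase and strip dots/whitespace: ``"f32.1" -> "F321"``."""
    return code.replace(".", "").strip().upper()


@dataclass(frozen=True)
class CodeSet:
    """A named set of code prefixes with optional exclusions."""

    name: str
    include_prefixes: tuple[str, ...]
    exclude_prefixes: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.include_prefixes:
            raise ValueError(f"code set {self.name!r} has no include prefixes")
        object.__setattr__(
            self, "include_prefixes", tuple(normalise_code(p) for p in self.include_prefixes)
        )
        object.__setattr__(
            self, "exclude_prefixes", tuple(normalise_code(p) for p in self.exclude_prefixes)
        )

    def matches(self, code: str) -> bool:
        return code_matches(code, self)


def code_matches(code: str, code_set: CodeSet) -> bool:
    """True iff the normalised code starts with an include and no exclude prefix."""
    if not code or not code.strip():
        raise ValueError("empty code")
    c = normalise_code(code)
    if any(c.startswith(p) for p in code_set.exclude_prefixes):
        return False
    return any(c.startswith(p) for p in code_set.include_prefixes)


def load_registry(path: str | Path) -> dict[str, CodeSet]:
    """Load a name → CodeSet registry from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _registry_from_mapping(raw)


def _registry_from_mapping(raw: dict) -> dict[str, CodeSet]:
    registry = {}
    for name, entry in raw.items():
        registry[name] = CodeSet(
            name=name,
            include_prefixes=tuple(entry["include"]),
            exclude_prefixes=tuple(entry.get("exclude", ())),
        )
    return registry


def default_registry() -> dict[str, CodeSet]:
    """The registry bundled with the package (see module docstring)."""
    ref = resources.files("depclaims").joinpath("code_registry.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _registry_from_mapping(raw)
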