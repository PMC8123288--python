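"""Bundled per-case parameter sets and baseline clinical values.

Ten advanced-HCC patients treated with sorafenib (Case-3 switched to
regorafenib): the published best-fit model parameters per case, the
baseline tumor volume and serum biomarker levels, and the mRECIST response
label of the target lesion (CR / PR / SD / PD).  Cases 1-3 are the
model set-up prototypes and additionally carry the printed initial cell
count ``c0`` and the CT-volume conversion ``kappa`` back-solved from it.

The values are shipped as package data (``data/case_fixtures.json``) and
verified against a SHA-256 checksum at load time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

from .model import ModelParameters

__all__ = ["CaseFixture", "load_case_fixtures", "RESPONSE_GROUPS", "response_group"]

_FIXTURE_SHA256 = "158120d87eabdc65c3f146b60c896006922dfb6c8591f934a1af295a593467a8"

#: cohort grouping of the ten cases by target-lesion response
RESPONSE_GROUPS = {"CR": (1, 4, 5, 6), "PR-SD": (2, 3, 7, 8), "PD": (9, 10)}


def response_group(label: str) -> str:
    """Map an mRECIST target-lesion label to its cohort group."""
    label = label.strip().upper()
    if label == "CR":
        return "CR"
    if label in ("PR", "SD", "PR-SD"):
        return "PR-SD"
    if label == "PD":
        return "PD"
    raise ValueError(f"unknown response label {label!r} (expected CR/PR/SD/PD)")


@dataclass(frozen=True)
class CaseFixture:
    """One bundled case: parameters plus baseline observations."""

    case_id: int
    params: ModelParameters
    response: str
    overall_response: str
    treatment: str
    duration_months: float
    baseline_ttv_cm3: float
    baseline_afp_ng_ml: float
    baseline_pivka_mau_ml: float
    c0: float | None

    @property
    def group(self) -> str:
        return response_group(self.response)


def load_case_fixtures() -> dict:
    """Load the ten bundled cases, keyed by case number (1..10).

    Raises ``ValueError`` if the embedded data file does not match its
    recorded checksum (guards against accidental edits).
    """
    raw = (resources.files("hccdyn") / "data" / "case_fixtures.json").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise ValueError(
            f"case fixture data checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    doc = json.loads(raw)
    out = {}
    for key, rec in doc["cases"].items():
        cid = int(key)
        out[cid] = CaseFixture(
            case_id=cid,
            params=ModelParameters.from_dict(rec["params"]),
            response=rec["response"],
            overall_response=rec["overall_response"],
            treatment=rec["treatment"],
            duration_months=float(rec["duration_months"]),
            baseline_ttv_cm3=float(rec["baseline"]["ttv_cm3"]),
            baseline_afp_ng_ml=float(rec["baseline"]["afp_ng_ml"]),
            baseline_pivka_mau_ml=float(rec["baseline"]["pivka_mau_ml"]),
            c0=None if rec["c0"] is None else float(rec["c0"]),
        )
    return out
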