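"""Packaged reference tables from an eight-patient knee-OA cell-therapy trial.

Three small CSVs ship with the package, transcribed from the trial report:

* ``trial_alterations.csv`` — per-patient before/after alterations of the
  projected cartilage area ratio (threshold 1.5 mm) and mean thickness in
  the four analysed regions.  ``before`` is the change over the ~30 weeks
  preceding the first injection (value at -1 w minus value at -30 w),
  ``after`` the change over the ~30 weeks following it (30 w minus -1 w).
* ``trial_reported_summary.csv`` — the medians, quartiles and p-values the
  report itself prints for those columns (kept separate from the
  per-patient data so regression tests can recompute one from the other).
* ``trial_demographics.csv`` — age, sex, BMI, injected side and
  Kellgren–Lawrence grade of the eight patients.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = [
    "load_trial_alterations",
    "load_trial_reported_summary",
    "load_trial_demographics",
    "fixture_sha256",
]

_CHECKSUMS = {
    "trial_alterations.csv": "80577ae02fe86343b67196461d2b7807b65ef40a3a5ed8f063588f518775021a",
    "trial_reported_summary.csv": "5d437dcaddb46647ddb5f73c23269b7a7d2707fa7bcf37be03c8ab78d2150793",
    "trial_demographics.csv": "acfd1c83f07d710b2ed7da51f72ac9927ef764191dd71dda42fec957d2855d03",
}


def _path(name: str):
    return resources.files("kneequant.data").joinpath(name)


def fixture_sha256(name: str, verify: bool = True) -> str:
    """SHA-256 of a packaged fixture; raises if it no longer matches the
    checksum frozen at packaging time."""
    digest = hashlib.sha256(_path(name).read_bytes()).hexdigest()
    if verify and digest != _CHECKSUMS[name]:
        raise ValueError(f"fixture {name} is corrupted (sha256 {digest})")
    return digest


def load_trial_alterations() -> pd.DataFrame:
    """Per-patient before/after alterations (long format)."""
    with resources.as_file(_path("trial_alterations.csv")) as p:
        return pd.read_csv(p, dtype={"patient_id": str})


def load_trial_reported_summary() -> pd.DataFrame:
    """Medians, quartiles and p-values as printed in the trial report."""
    with resources.as_file(_path("trial_reported_summary.csv")) as p:
        return pd.read_csv(p)


def load_trial_demographics() -> pd.DataFrame:
    with resources.as_file(_path("trial_demographics.csv")) as p:
        return pd.read_csv(p, dtype={"patient_id": str})
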