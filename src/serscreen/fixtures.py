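"""The bundled 40-sample reference cohort and cohort-table loading.

The package ships the published 40-sample pickled-vegetable screening
table — per-sample Z-ratio of the benzoic-acid monomer (column A),
Z-ratio of the dimer (column B), their sum, and the reference HPLC
concentration in ppm — as checksummed delimited text.  It is the
benchmark every evaluation routine is exercised against.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from .evaluation import CohortEntry, LabeledCohort

__all__ = ["FixtureCorruptionError", "load_table2", "load_table2_frame", "load_cohort_csv"]

_TABLE2_SHA256 = "8dceeca0331edebb3cb3c43a9816f3ff6ca390e33f52e9726226bf3da6bc3cd4"


class FixtureCorruptionError(RuntimeError):
    """Bundled fixture bytes do not match the recorded checksum."""


def _table2_bytes() -> bytes:
    return resources.files("serscreen").joinpath("data/table2.csv").read_bytes()


def load_table2_frame(verify: bool = True) -> pd.DataFrame:
    """The reference table as a DataFrame (columns: no, z_ratio_monomer,
    z_ratio_dimer, sum, hplc_ppm)."""
    raw = _table2_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _TABLE2_SHA256:
            raise FixtureCorruptionError(
                f"reference table checksum mismatch: {digest} != {_TABLE2_SHA256}"
            )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_table2(regulatory_limit: float = 600.0, verify: bool = True) -> LabeledCohort:
    """The reference cohort: 40 samples, sum-of-Z-ratio score vs HPLC ppm."""
    df = load_table2_frame(verify=verify)
    entries = [
        CohortEntry(sample_id=str(int(r.no)), sum_score=float(r.sum), hplc_ppm=float(r.hplc_ppm))
        for r in df.itertuples(index=False)
    ]
    return LabeledCohort(entries, regulatory_limit=regulatory_limit)


def load_cohort_csv(path: str | Path, regulatory_limit: float = 600.0) -> LabeledCohort:
    """Load a user cohort table.

    Expected columns: ``sample_id``, ``hplc_ppm``, and either a
    precomputed ``sum_score`` or the pair ``z_ratio_monomer`` /
    ``z_ratio_dimer`` (summed on load).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if not {"sample_id", "hplc_ppm"} <= cols:
        raise ValueError(f"{path}: cohort table needs sample_id and hplc_ppm columns")
    if "sum_score" in cols:
        scores = df["sum_score"].astype(float)
    elif {"z_ratio_monomer", "z_ratio_dimer"} <= cols:
        scores = df["z_ratio_monomer"].astype(float) + df["z_ratio_dimer"].astype(float)
    else:
        raise ValueError(
            f"{path}: need sum_score or z_ratio_monomer + z_ratio_dimer columns"
        )
    entries = [
        CohortEntry(str(sid), float(sc), float(ppm))
        for sid, sc, ppm in zip(df["sample_id"], scores, df["hplc_ppm"])
    ]
    return LabeledCohort(entries, regulatory_limit=regulatory_limit)
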