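"""Temperature-Humidity Index (THI) for heat-stress classification.

THI combines mean air temperature (Celsius) and mean relative humidity
(percent) into a single heat-load proxy for livestock:

    THI = (1.8*T + 32) - (0.55 - 0.0055*RH) * (1.8*T - 26)

A location is classified heat-stressed when THI strictly exceeds the
threshold (72 by convention for poultry).  Two identities are handy sanity
checks: at RH = 100 the second term vanishes and THI = 1.8*T + 32; at
1.8*T = 26 (T = 130/9 C) THI = 58 regardless of humidity.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

HEAT_STRESS_THRESHOLD = 72.0


@dataclass(frozen=True)
class ClimateRecord:
    location: str
    t_avg: float   # mean air temperature, degrees Celsius
    rh_avg: float  # mean relative humidity, percent (0-100)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh_avg <= 100.0:
            raise ValueError(
                f"{self.location}: relative humidity must be in [0, 100], "
                f"got {self.rh_avg}")


@dataclass(frozen=True)
class ThiResult:
    location: str
    thi: float
    heat_stressed: bool


def compute_thi(rec: ClimateRecord) -> float:
    """Evaluate the THI formula exactly (no rounding)."""
    return (1.8 * rec.t_avg + 32.0) - (0.55 - 0.0055 * rec.rh_avg) * (1.8 * rec.t_avg - 26.0)


def classify_heat_stress(
        records: list[ClimateRecord],
        threshold: float = HEAT_STRESS_THRESHOLD,
) -> tuple[list[ThiResult], list[ThiResult]]:
    """Partition locations into (heat_stressed, not_stressed).

    The comparison is strict: THI == threshold is *not* heat-stressed.
    """
    stressed, cool = [], []
    for rec in records:
        thi = compute_thi(rec)
        res = ThiResult(rec.location, thi, thi > threshold)
        (stressed if res.heat_stressed else cool).append(res)
    return stressed, cool


def read_climate_csv(path: str | os.PathLike) -> list[ClimateRecord]:
    """Read ``location,t_avg,rh_avg`` CSV (header required)."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(ClimateRecord(
                location=row["location"],
                t_avg=float(row["t_avg"]),
                rh_avg=float(row["rh_avg"]),
            ))
    return records


def write_thi_table(results: list[ThiResult], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("location\tthi\theat_stressed\n")
        for r in results:
            fh.write(f"{r.location}\t{r.thi:.6g}\t{str(r.heat_stressed).lower()}\n")
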