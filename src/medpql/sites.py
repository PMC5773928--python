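"""Reference station table and run-design arithmetic.

The packaged table lists the 11 reference NOAA ISD airport stations for the
continental-US Medfly quarantine analysis, with the coordinates and record
start years needed for nearest-site matching and for sizing the full
simulation campaign.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .weather import SiteMeta

__all__ = ["load_reference_sites", "reference_pql_end_date", "planned_total_simulations"]


def _raw_table() -> dict:
    with resources.files("medpql.data").joinpath("sites_noaa.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_reference_sites() -> list[SiteMeta]:
    """The 11 reference stations, ordered by latitude (north to south)."""
    return [
        SiteMeta(
            callsign=row["callsign"],
            name=row["name"],
            latitude=float(row["latitude"]),
            longitude=float(row["longitude"]),
            elevation=float(row["elevation"]),
            start_year=int(row["start_year"]),
        )
        for row in _raw_table()["sites"]
    ]


def reference_pql_end_date() -> pd.Timestamp:
    """Last start date for which PQLs were generated in the reference design."""
    return pd.Timestamp(_raw_table()["pql_end_date"])


def planned_total_simulations(
    sites=None,
    end_date=None,
    every_days: int = 7,
    n_sims: int = 2500,
) -> int:
    """Simulation count implied by the station table and the run design.

    One run every ``every_days`` days from each site's record start
    (January 1 of ``start_year``) through ``end_date``, inclusive, with
    ``n_sims`` simulations per run, summed over sites.
    """
    sites = load_reference_sites() if sites is None else list(sites)
    end = reference_pql_end_date() if end_date is None else pd.Timestamp(end_date)
    total = 0
    for s in sites:
        start = pd.Timestamp(year=s.start_year, month=1, day=1)
        days = (end - start).days
        if days < 0:
            continue
        total += (days // every_days + 1) * n_sims
    return total
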