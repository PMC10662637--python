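"""Reading and writing input bundles as delimited text plus a YAML manifest.

Every quantity is one comma-separated UTF-8 file with a header row. Single-
age tables use columns ``age, gender, year, value`` (base-year-only tables
carry the base year in the year column); grouped tables use
``age_lo, age_hi, gender[, year], value``; the prevalence file adds a
``status`` column with values never/current/former. A manifest names each
file and declares its age convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inputs import CountryBundle, ReferenceBundle, expand_groups_uniform, smooth_group_prevalence
from .tables import AgeGenderYearTable, GroupedTable, SchemaError

COUNTRY_KEYS = ("population", "overall_mortality", "le_overall_base", "smoking_prevalence_base")
REFERENCE_KEYS = (
    "init", "cess", "mort_never", "mort_current", "mort_former",
    "le_never", "prev_base", "le_overall_base", "overall_mortality",
)


def _read_single(path: Path, ages, years) -> AgeGenderYearTable:
    tbl = AgeGenderYearTable.from_frame(pd.read_csv(path))
    if not (np.array_equal(tbl.ages, ages) and np.array_equal(tbl.years, years)):
        raise SchemaError(f"{path} does not cover the declared ages/years")
    return tbl


def _read_quantity(entry: dict, base: Path, ages, years, *, smooth: bool = False):
    path = base / entry["path"]
    convention = entry.get("ages", "single")
    if convention == "single":
        return _read_single(path, ages, years)
    if convention != "grouped":
        raise SchemaError(f"unknown age convention {convention!r}")
    grouped = GroupedTable(pd.read_csv(path))
    if smooth:
        return smooth_group_prevalence(grouped, ages)
    return expand_groups_uniform(grouped, ages, years if grouped.has_year else None)


def _read_prevalence(entry: dict, base: Path, ages, base_year: int) -> dict:
    df = pd.read_csv(base / entry["path"])
    if "status" not in df.columns:
        raise SchemaError("prevalence file needs a status column")
    convention = entry.get("ages", "single")
    out = {}
    for status in ("never", "current", "former"):
        sub = df[df["status"] == status].drop(columns="status")
        if convention == "grouped":
            tbl = smooth_group_prevalence(GroupedTable(sub), ages)
        else:
            if "year" not in sub.columns:
                sub = sub.assign(year=base_year)
            tbl = AgeGenderYearTable.from_frame(sub)
        out[status] = AgeGenderYearTable(tbl.values, ages, np.array([base_year]))
    if convention == "grouped":
        # smoothing the three curves independently need not preserve the
        # sum-to-one constraint exactly; close the system on never use
        total = sum(t.values for t in out.values())
        out["never"] = AgeGenderYearTable(
            out["never"].values + (1.0 - total), ages, np.array([base_year])
        )
    return out


def read_bundles(manifest_path) -> tuple:
    """Read (CountryBundle, ReferenceBundle) per a YAML manifest."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        man = yaml.safe_load(fh)
    base = manifest_path.parent
    base_year, end_year = int(man["base_year"]), int(man["end_year"])
    min_age, max_age = int(man["min_age"]), int(man["max_age"])
    ages = np.arange(min_age, max_age + 1)
    years = np.arange(base_year, end_year + 1)
    base_years = np.array([base_year])

    ci = man["inputs"]
    country = CountryBundle(
        population=_read_quantity(ci["population"], base, ages, years),
        overall_mortality=_read_quantity(ci["overall_mortality"], base, ages, years),
        le_overall_base=_read_quantity(ci["le_overall_base"], base, ages, base_years),
        smoking_prevalence_base=_read_prevalence(
            ci["smoking_prevalence_base"], base, ages, base_year
        ),
        base_year=base_year,
        end_year=end_year,
        min_age=min_age,
        max_age=max_age,
    )
    ri = man["reference"]
    reference = ReferenceBundle(
        init=_read_quantity(ri["init"], base, ages, years),
        cess=_read_quantity(ri["cess"], base, ages, years),
        mort_never=_read_quantity(ri["mort_never"], base, ages, years),
        mort_current=_read_quantity(ri["mort_current"], base, ages, years),
        mort_former=_read_quantity(ri["mort_former"], base, ages, years),
        le_never=_read_quantity(ri["le_never"], base, ages, years),
        prev_base=_read_prevalence(ri["prev_base"], base, ages, base_year),
        le_overall_base=_read_quantity(ri["le_overall_base"], base, ages, base_years),
        overall_mortality=_read_quantity(ri["overall_mortality"], base, ages, years),
    )
    switching = None
    if "switching" in man:
        switching = GroupedTable(pd.read_csv(base / man["switching"]["path"]))
    return country, reference, switching


def write_bundles(country: CountryBundle, reference: ReferenceBundle, out_dir,
                  switching: GroupedTable | None = None) -> Path:
    """Write both bundles as CSVs plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man: dict = {
        "base_year": country.base_year,
        "end_year": country.end_year,
        "min_age": country.min_age,
        "max_age": country.max_age,
        "inputs": {},
        "reference": {},
    }

    def _write_table(tbl: AgeGenderYearTable, name: str) -> dict:
        tbl.to_frame().to_csv(out / f"{name}.csv", index=False)
        return {"path": f"{name}.csv", "ages": "single", "units": _UNITS.get(name, "value")}

    def _write_prev(prev: dict, name: str) -> dict:
        frames = [t.to_frame().assign(status=s) for s, t in prev.items()]
        pd.concat(frames).to_csv(out / f"{name}.csv", index=False)
        return {"path": f"{name}.csv", "ages": "single", "units": "proportion"}

    man["inputs"]["population"] = _write_table(country.population, "population")
    man["inputs"]["overall_mortality"] = _write_table(country.overall_mortality, "overall_mortality")
    man["inputs"]["le_overall_base"] = _write_table(country.le_overall_base, "le_overall_base")
    man["inputs"]["smoking_prevalence_base"] = _write_prev(
        country.smoking_prevalence_base, "smoking_prevalence_base"
    )
    for key in REFERENCE_KEYS:
        obj = getattr(reference, key)
        name = f"ref_{key}"
        if key == "prev_base":
            man["reference"][key] = _write_prev(obj, name)
        else:
            man["reference"][key] = _write_table(obj, name)
    if switching is not None:
        switching.data.to_csv(out / "switching.csv", index=False)
        man["switching"] = {"path": "switching.csv", "ages": "grouped", "units": "probability/yr"}
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(man, fh, sort_keys=False)
    return manifest_path


_UNITS = {
    "population": "persons",
    "overall_mortality": "probability/yr",
    "le_overall_base": "years",
    "ref_init": "probability/yr",
    "ref_cess": "probability/yr",
    "ref_mort_never": "probability/yr",
    "ref_mort_current": "probability/yr",
    "ref_mort_former": "probability/yr",
    "ref_le_never": "years",
    "ref_le_overall_base": "years",
    "ref_overall_mortality": "probability/yr",
}
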