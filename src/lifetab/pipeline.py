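"""Study orchestration: standard tables, extension, per-type imputation,
abridged reports, HALE, and between-group difference tables.

The workflow mirrors how such registry studies are run: complete smoothed life
tables for the reference and the pooled (standard) subgroup population; old-age
extension of rates; for each sparse type, imputation of missing age-specific
rates from the standard table; abridged reporting at 5-year starts; Sullivan
HALE under the requested prevalence definitions; and a differences table
(reference minus group) at each report age.

Re-running with the same config and inputs is byte-identical: nothing in this
module draws random numbers (the config seed exists for resampling add-ons).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import LifetabError, ScheduleValidationError, StageError
from .extension import ExtensionConfig
from .imputation import DEFAULT_GROUP_STARTS, RateLinkModel, abridge
from .lifetable import LifeTableModel, LifeTableResults
from .schedules import (
    SEXES,
    MortalitySchedule,
    prevalence_from_frame,
    read_mortality_csv,
    read_prevalence_csv,
    schedules_from_frame,
)
from .sullivan import SullivanModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one study run."""

    mortality_csv: str = ""
    prevalence_csv: str | None = None
    reference_group: str = "reference"
    standard_group: str = "disabled"
    sexes: tuple[str, ...] = SEXES
    hale_definitions: tuple[str, ...] = ("NHIS",)
    report_age_starts: tuple[int, ...] = DEFAULT_GROUP_STARTS
    extension: ExtensionConfig | None = None
    extension_overrides: dict = field(default_factory=dict)  # group_id -> family
    smooth_order: int | None = 9
    radix: float = 100_000.0
    output_dir: str = "lifetab_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        ext = payload.pop("extension", None)
        cfg = cls(**payload)
        if ext:
            if isinstance(ext, dict):
                ext.pop("enabled", None)
                for key in ("families",):
                    if key in ext:
                        ext[key] = tuple(ext[key])
                for key in ("fit_window",):
                    if key in ext:
                        ext[key] = tuple(ext[key])
                cfg.extension = ExtensionConfig(**ext)
            else:
                cfg.extension = ext
        for key in ("sexes", "hale_definitions", "report_age_starts"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StudyReport:
    """Bundle of every output of one run."""

    results: dict          # (sex, group) -> LifeTableResults
    hale: dict             # (sex, group, definition) -> SullivanResults
    abridged: dict         # (sex, group) -> DataFrame (report layout)
    differences: dict      # sex -> DataFrame
    manifest: dict

    def write(self, output_dir) -> Path:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (sex, gid), res in self.results.items():
            res.to_csv(out / f"lifetable_{gid}_{sex}.csv")
        for (sex, gid), frame in self.abridged.items():
            frame.to_csv(out / f"abridged_{gid}_{sex}.csv", index=False)
        for sex, frame in self.differences.items():
            frame.to_csv(out / f"differences_{sex}.csv", index=False)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)
        return out


def _abridged_report(res: LifeTableResults, hale_results: dict, starts) -> pd.DataFrame:
    ab = abridge(res.table, starts, group_id=res.group_id, sex=res.sex)
    frame = ab.frame[["age_group", "start", "ex", "se_ex", "lo95", "hi95"]].copy()
    for definition, sres in hale_results.items():
        ht = sres.hale_table
        idx = np.searchsorted(ht.ages, frame["start"].to_numpy())
        frame[f"hale_{definition}"] = ht.hale[idx]
        if ht.se_hale is not None:
            frame[f"hale_{definition}_lo95"] = ht.lo95[idx]
            frame[f"hale_{definition}_hi95"] = ht.hi95[idx]
    return frame


def difference_report(
    tables: dict, reference_id: str, ages=None
) -> pd.DataFrame:
    """Reference-minus-group differences of ex (and any hale_* column).

    ``tables`` maps group_id to a frame with an ``age`` (or ``start``) column,
    ``ex``, and optional ``hale_<definition>`` columns. Differences are computed
    on full precision; the ``*_printed`` columns re-derive them from 2-decimal
    rounded inputs for concordance with published tables. Missing age rows in
    any group raise an error.
    """
    if reference_id not in tables:
        raise KeyError(f"reference group {reference_id!r} not among tables")

    def norm(frame):
        frame = frame.copy()
        if "age" not in frame.columns:
            frame = frame.rename(columns={"start": "age"})
        return frame

    ref = norm(tables[reference_id])
    if ages is None:
        ages = ref["age"].tolist()
    value_cols = ["ex"] + [c for c in ref.columns if c.startswith("hale_")
                           and not c.endswith(("lo95", "hi95"))]
    rows = []
    for gid, frame in tables.items():
        if gid == reference_id:
            continue
        frame = norm(frame)
        for age in ages:
            r = ref[ref["age"] == age]
            g = frame[frame["age"] == age]
            if r.empty or g.empty:
                raise LifetabError(
                    f"missing age {age} row for group {gid!r} or reference"
                )
            row = {"group_id": gid, "age": age}
            for col in value_cols:
                if col not in frame.columns or col not in ref.columns:
                    continue
                rv, gv = float(r[col].iloc[0]), float(g[col].iloc[0])
                row[f"{col}_diff"] = rv - gv
                row[f"{col}_diff_printed"] = round(round(rv, 2) - round(gv, 2), 2)
            rows.append(row)
    return pd.DataFrame(rows)


def run_study(
    config: RunConfig,
    mortality: pd.DataFrame | None = None,
    prevalence: pd.DataFrame | None = None,
) -> StudyReport:
    """Execute the full workflow; any stage failure raises :class:`StageError`."""
    if mortality is None:
        mortality = read_mortality_csv(config.mortality_csv)
    if prevalence is None and config.prevalence_csv:
        prevalence = read_prevalence_csv(config.prevalence_csv)

    schedules = schedules_from_frame(mortality)
    groups = sorted({gid for gid, _ in schedules})
    for required in (config.reference_group, config.standard_group):
        if required not in groups:
            raise ScheduleValidationError(f"group {required!r} absent from inputs")

    results, hale, abridged, differences = {}, {}, {}, {}
    warnings_log: list[str] = []
    selected_families: dict[str, str] = {}
    link_params: dict[str, dict] = {}

    def ext_for(gid):
        if config.extension is None:
            return None
        fam = config.extension_overrides.get(gid)
        if fam:
            return dataclasses.replace(config.extension, family_override=fam)
        return config.extension

    for sex in config.sexes:
        sex_groups = [gid for gid in groups if (gid, sex) in schedules]
        if config.reference_group not in sex_groups:
            continue

        def fit_table(gid, stage):
            sched = schedules[(gid, sex)]
            try:
                if np.all(sched.observed):
                    res = LifeTableModel(
                        sched, smooth_order=config.smooth_order,
                        extension=ext_for(gid), radix=config.radix,
                    ).fit()
                else:
                    std = results[(sex, config.standard_group)]
                    linkres = RateLinkModel(sched, std.table).fit()
                    link_params[f"{gid}/{sex}"] = linkres.params
                    if linkres.link.fallback:
                        warnings_log.append(
                            f"constant-offset link fallback for {gid}/{sex}"
                        )
                    res = LifeTableModel(
                        linkres.imputed, smooth_order=config.smooth_order,
                        radix=config.radix,
                    ).fit()
                if res.extension_fit is not None:
                    selected_families[f"{gid}/{sex}"] = res.extension_fit.family
                return res
            except LifetabError as exc:
                raise StageError(stage, f"{gid}/{sex}", str(exc)) from exc

        results[(sex, config.reference_group)] = fit_table(
            config.reference_group, "reference_table"
        )
        if config.standard_group != config.reference_group:
            results[(sex, config.standard_group)] = fit_table(
                config.standard_group, "standard_table"
            )
        for gid in sex_groups:
            if (sex, gid) in results:
                continue
            results[(sex, gid)] = fit_table(gid, "type_table")

        for gid in sex_groups:
            res = results[(sex, gid)]
            group_hale = {}
            for definition in config.hale_definitions:
                if prevalence is None:
                    break
                try:
                    prev = prevalence_from_frame(prevalence, definition, gid, sex)
                except ScheduleValidationError:
                    warnings_log.append(
                        f"no {definition} prevalence for {gid}/{sex}; HALE skipped"
                    )
                    continue
                try:
                    group_hale[definition] = SullivanModel(res, prev).fit()
                except LifetabError as exc:
                    raise StageError("hale", f"{gid}/{sex}", str(exc)) from exc
            for definition, sres in group_hale.items():
                hale[(sex, gid, definition)] = sres
            try:
                abridged[(sex, gid)] = _abridged_report(
                    res, group_hale, config.report_age_starts
                )
            except LifetabError as exc:
                raise StageError("abridge", f"{gid}/{sex}", str(exc)) from exc

        # each group is compared at the report ages it shares with the reference
        ref_frame = abridged[(sex, config.reference_group)]
        parts = []
        for gid in sex_groups:
            if gid == config.reference_group:
                continue
            common = sorted(
                set(ref_frame["start"]) & set(abridged[(sex, gid)]["start"])
            )
            parts.append(
                difference_report(
                    {config.reference_group: ref_frame, gid: abridged[(sex, gid)]},
                    config.reference_group,
                    ages=common,
                )
            )
        differences[sex] = (
            pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
        )

    manifest = {
        "config_digest": config.digest(),
        "config": dataclasses.asdict(config),
        "groups": groups,
        "selected_extension_families": selected_families,
        "rate_links": link_params,
        "warnings": warnings_log,
    }
    return StudyReport(
        results=results, hale=hale, abridged=abridged,
        differences=differences, manifest=manifest,
    )
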