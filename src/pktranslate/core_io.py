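"""Shared domain types, dataset/report I/O and pipeline orchestration.

Unit conventions (applied throughout the package, converted only at I/O
boundaries): concentration ng/mL, time h, dose mg/kg (basis="per_kg") or mg
(basis="absolute"), clearance L/h with explicit per-kg variants, volume L.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SPECIES_NAMES = ("mouse", "rat", "dog", "monkey", "human")
ROUTES = ("iv_bolus", "oral")
SEXES = ("M", "F")

#: mandatory columns of the concentration CSV dialect
DATASET_COLUMNS = [
    "subject_id", "species", "sex", "group", "route", "dose", "dose_units",
    "matrix", "time_h", "conc_ng_per_ml",
]


class SchemaError(ValueError):
    """A dataset file does not match the declared dialect."""


class UnitError(ValueError):
    """Inconsistent or unsupported units; never silently rescaled."""


@dataclass(frozen=True)
class ConcentrationRecord:
    subject_id: str
    species: str
    sex: str
    group: str
    route: str
    dose: float
    dose_basis: str          # "per_kg" (mg/kg) or "absolute" (mg)
    matrix: str
    time_h: float
    conc_ng_per_ml: float
    below_lloq: bool = False

    def __post_init__(self) -> None:
        if self.species not in SPECIES_NAMES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.time_h < 0:
            raise ValueError(f"negative time {self.time_h}")
        if self.conc_ng_per_ml < 0:
            raise ValueError(f"negative concentration {self.conc_ng_per_ml}")


@dataclass
class StudyDataset:
    """Long-format concentration-time study with dosing metadata.

    The lingua franca of the NCA, absorption-fitting and PBPK-validation
    stages.  ``records`` is a DataFrame with DATASET_COLUMNS plus a
    ``below_lloq`` flag column.
    """

    records: pd.DataFrame
    label: str = "study"
    lloq: float = 0.0

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"dataset missing mandatory column(s): {missing}")
        if len(df) == 0:
            raise ValueError("dataset is empty")
        if "below_lloq" not in df.columns:
            df = df.copy()
            df["below_lloq"] = df["conc_ng_per_ml"] < self.lloq
            self.records = df
        neg_t = df.index[df["time_h"] < 0]
        if len(neg_t):
            raise ValueError(f"negative time at row(s) {list(neg_t[:5])}")
        neg_c = df.index[df["conc_ng_per_ml"] < 0]
        if len(neg_c):
            raise ValueError(f"negative concentration at row(s) {list(neg_c[:5])}")
        units = df["dose_units"].unique()
        if len(units) > 1:
            raise UnitError(f"mixed dose units in one dataset: {sorted(units)}")
        for (subj, matrix), g in df.groupby(["subject_id", "matrix"], sort=False):
            t = g["time_h"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"times not strictly increasing for subject {subj!r}, matrix {matrix!r}"
                )

    @property
    def dose_units(self) -> str:
        return str(self.records["dose_units"].iloc[0])

    def profile(self, subject_id: str, matrix: str = "plasma") -> pd.DataFrame:
        df = self.records
        sel = df[(df["subject_id"] == subject_id) & (df["matrix"] == matrix)]
        return sel.sort_values("time_h")

    def mean_profile(self, matrix: str = "plasma",
                     route: str | None = None,
                     group: str | None = None,
                     drop_blq: bool = True) -> pd.DataFrame:
        """Arithmetic mean concentration per timepoint, pooled across subjects."""
        df = self.records
        sel = df[df["matrix"] == matrix]
        if route is not None:
            sel = sel[sel["route"] == route]
        if group is not None:
            sel = sel[sel["group"] == group]
        if drop_blq:
            sel = sel[~sel["below_lloq"]]
        if len(sel) == 0:
            raise ValueError("no records match the requested profile")
        out = (sel.groupby("time_h", as_index=False)["conc_ng_per_ml"]
               .mean().sort_values("time_h"))
        return out


@dataclass(frozen=True)
class DrugProperties:
    """Physicochemical and binding constants of a compound."""

    mw: float                                  # g/mol
    pka_list: tuple[tuple[float, str], ...]    # (value, "acid"|"base")
    logp: float
    solubility: float                          # ug/mL at stated pH
    papp: float                                # 1e-6 cm/s
    fup_by_species: Mapping[str, float]        # fraction (0, 1]
    bp_ratio: float                            # blood:plasma, unitless
    kp_overrides: Mapping[str, float] = field(default_factory=dict)
    cl_plasma_per_kg: Mapping[str, float] = field(default_factory=dict)  # L/h/kg
    cl_biliary_per_kg: float = 0.0             # L/h/kg
    ka: float | None = None                    # 1/h

    def __post_init__(self) -> None:
        if not np.isfinite(self.logp):
            raise ValueError("logp must be finite")
        for pka, kind in self.pka_list:
            if kind not in ("acid", "base"):
                raise ValueError(f"pKa type must be 'acid' or 'base', got {kind!r}")
        for sp, fu in self.fup_by_species.items():
            if not 0 < fu <= 1:
                raise ValueError(f"fup for {sp} outside (0, 1]: {fu}")
        if self.bp_ratio <= 0:
            raise ValueError("bp_ratio must be positive")
        for tis, kp in self.kp_overrides.items():
            if kp <= 0:
                raise ValueError(f"Kp override for {tis} must be positive")

    def fup(self, species: str) -> float:
        try:
            return self.fup_by_species[species]
        except KeyError:
            raise KeyError(f"no fup recorded for species {species!r}") from None


# ---------------------------------------------------------------------------
# dataset reading / writing


def read_dataset(path: str | Path, label: str | None = None,
                 lloq: float = 0.0) -> StudyDataset:
    """Read a concentration CSV (comma-separated, UTF-8, header mandatory).

    Below-LLOQ values are flagged, never dropped.  Dose basis is inferred
    from dose_units ("mg/kg" -> per_kg, "mg" -> absolute).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    return StudyDataset(records=df[DATASET_COLUMNS].copy(),
                        label=label or path.stem, lloq=lloq)


def write_dataset(dataset: StudyDataset, path: str | Path) -> None:
    dataset.records[DATASET_COLUMNS].to_csv(path, index=False)


def _sig3(x) -> str:
    """Render a number at 3 significant figures (report convention)."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        if not np.isfinite(x):
            return str(x)
        if x == 0:
            return "0"
        return f"{float(f'{x:.3g}'):g}"
    return str(x)


def write_report(tables: Sequence[tuple[str, pd.DataFrame]],
                 path: str | Path) -> list[Path]:
    """Write result tables as TSV, one file per table, 3 significant figures.

    ``tables`` is a sequence of (name, DataFrame); column order is preserved
    deterministically.  Returns the written paths.
    """
    if not tables:
        raise ValueError("no tables to write")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables:
        out = outdir / f"{name}.tsv"
        rendered = df.copy()
        for col in rendered.columns:
            rendered[col] = rendered[col].map(_sig3)
        rendered.to_csv(out, sep="\t", index=False)
        written.append(out)
    return written


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# configuration and pipeline


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a mapping at top level")
    return cfg


def _canonical(obj):
    if isinstance(obj, Mapping):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(),
                                                         key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    return obj


def config_hash(config: Mapping) -> str:
    canon = json.dumps(_canonical(config), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: Mapping, out: str | Path, seed: int = 0) -> dict:
    """Run the translation pipeline stages declared in ``config``.

    Stages, in order: ``synthetic`` (generate study data), ``nca``,
    ``ka`` (absorption fit), ``allometry``, ``dose``, ``pbpk``.  Stages
    without a config section are skipped; any stage failure aborts with the
    stage name.  Writes TSV reports plus a JSON run manifest (seed, config
    hash) under ``out`` and returns a dict of stage results.
    """
    from . import allometry, fih_dose, ka_fit, nca, pbpk, synthetic
    from .physiology import get_species
    from .reference import drug_properties_from_config

    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    tables: list[tuple[str, pd.DataFrame]] = []
    stage = "setup"
    try:
        drug = drug_properties_from_config(config.get("drug", {}))

        stage = "synthetic"
        datasets: dict[str, StudyDataset] = {}
        for name, spec in (config.get("synthetic") or {}).items():
            gspec = synthetic.GeneratorSpec(
                design=spec["design"], true_params=spec["true_params"],
                n_subjects=spec.get("n_subjects", 3),
                timepoints=spec.get("timepoints"),
                noise_cv=spec.get("noise_cv", 0.0),
                seed=seed + spec.get("seed_offset", 0),
                species=spec.get("species", "rat"),
            )
            ds, manifest = synthetic.generate(gspec)
            datasets[name] = ds
            write_dataset(ds, outdir / f"{name}.csv")
            with open(outdir / f"{name}.manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=float)
        results["datasets"] = datasets

        stage = "nca"
        if "studies" in config:
            nca_rows = []
            for name in config["studies"]:
                ds = datasets[name]
                summary = nca.nca_summary(ds)
                summary.insert(0, "study", name)
                nca_rows.append(summary)
            results["nca"] = pd.concat(nca_rows, ignore_index=True)
            tables.append(("nca_parameters", results["nca"]))

        stage = "ka"
        if "ka" in config:
            fits = {}
            for sp_name, profile_cfg in config["ka"]["profiles"].items():
                ds = datasets[profile_cfg["study"]]
                prof = ds.mean_profile(route="oral", group=profile_cfg.get("group"))
                fit = ka_fit.fit_onecomp(prof["time_h"].to_numpy(),
                                         prof["conc_ng_per_ml"].to_numpy(),
                                         dose=profile_cfg["dose"])
                fits[sp_name] = fit
            policy = ka_fit.ka_policy({k: v for k, v in fits.items()})
            results["ka"] = policy
            tables.append(("ka_policy", pd.DataFrame([{
                "typical_per_h": policy.typical, "low_per_h": policy.low,
                "high_per_h": policy.high}])))

        stage = "allometry"
        if "allometry" in config:
            acfg = config["allometry"]
            preds = allometry.predictions_from_reference(
                acfg.get("reference_values", {}))
            cl_value = allometry.aggregate(
                [p for p in preds if p.parameter == "cl"],
                policy=acfg.get("cl_policy", "mean"))
            vss_value = allometry.aggregate(
                [p for p in preds if p.parameter == "vss"],
                policy=acfg.get("vss_policy", "mean"))
            results["allometry"] = {"cl_ml_min": cl_value.value,
                                    "vss_l": vss_value.value}
            tables.append(("human_pk_predictions", pd.DataFrame([
                {"parameter": "CL_iv (mL/min)", "value": cl_value.value},
                {"parameter": "Vss (L)", "value": vss_value.value},
            ])))

        stage = "dose"
        if "dose" in config:
            plan, dose_tables = fih_dose.dose_stage(config["dose"])
            results["dose"] = plan
            tables.extend(dose_tables)

        stage = "pbpk"
        if "pbpk" in config:
            pcfg = config["pbpk"]
            species = get_species(pcfg.get("species", "human"))
            model = pbpk.build_model(
                drug, species,
                overrides=pcfg.get("overrides", {}),
                ka=pcfg.get("ka", drug.ka or 1.0),
                f_abs=pcfg.get("f_abs", 1.0),
                ehc_enabled=pcfg.get("ehc_enabled", True),
                reabsorption_fraction=pcfg.get("reabsorption_fraction", 0.9),
            )
            regimen = [(d.get("time", 0.0), d["route"], d["dose_mg"])
                       for d in pcfg["regimen"]]
            sim = pbpk.simulate(model, regimen, t_end=pcfg.get("t_end", 24.0))
            export = sim.to_frame(compartments=pcfg.get(
                "export", ["plasma", "liver"]))
            export.to_csv(outdir / "pbpk_profiles.csv", index=False)
            results["pbpk"] = sim
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if tables:
        write_report(tables, outdir)
    manifest = {
        "seed": seed,
        "config_hash": config_hash(dict(config)),
        "stages": [name for name in
                   ("synthetic", "studies", "ka", "allometry", "dose", "pbpk")
                   if name in config],
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
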