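"""Readers, writers and run configuration.

Tables are CSV (comma, UTF-8, '.' decimal) or TSV (sniffed), first column =
sample id.  Reconstructions use a small JSON schema (id, metabolites,
reactions with stoichiometry and bounds, biomass id, exchange ids); an
SBML-subset import is provided through cobra when available.  Every output
table written by the pipeline carries a header comment with the config hash
and seed so that downstream stages can refuse mixed-config inputs.
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

from .associations import StudyTables
from .community import Metabolite, Reaction, Reconstruction
from .errors import FormatError, ValidationError
from .sem import SEMCohort, SEMParameters

logger = logging.getLogger(__name__)

_RECON_REQUIRED = ("id", "metabolites", "reactions", "biomass_reaction")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline knobs in one place (CLI flags mirror these fields)."""

    seed: int = 0
    n_permutations: int = 5000
    alpha: float = 0.05
    min_prevalence: float = 0.10
    min_nonzero: float = 0.50
    coupling_coefficient: float = 400.0
    biomass_bounds: tuple[float, float] = (0.4, 1.0)
    robust_se_flavor: str = "HC1"
    diet_path: str | None = None
    output_dir: str = "."
    significant_only: bool = False

    def validate(self) -> None:
        if self.n_permutations < 100:
            raise ValidationError("n_permutations must be >= 100")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        for name in ("min_prevalence", "min_nonzero"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0, 1)")
        lo, hi = self.biomass_bounds
        if lo > hi:
            raise ValidationError("biomass_bounds must be ordered")
        if self.robust_se_flavor not in ("HC1", "HC3"):
            raise ValidationError("robust_se_flavor must be HC1 or HC3")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "biomass_bounds" in raw:
            raw["biomass_bounds"] = tuple(raw["biomass_bounds"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["biomass_bounds"] = list(self.biomass_bounds)
        return d

    @property
    def config_hash(self) -> str:
        # output_dir is plumbing, not analysis config: identical runs into
        # different directories must produce identical tables.
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        return hashlib.md5(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, comment="#")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample ids {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise FormatError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        df[col] = coerced
    return df


def read_study_tables(
    abundance_path: str | Path,
    metabolome_path: str | Path,
    covariates_path: str | Path,
    flux_path: str | Path | None = None,
) -> StudyTables:
    """Load and align the study tables on the intersection of sample ids.

    Abundance rows are renormalized to sum exactly 1 when they are within 1%
    of 1 already; rows further off raise a format error naming the sample.
    """
    abundance = _read_table(abundance_path)
    metabolome = _read_table(metabolome_path)
    covariates = _read_table(covariates_path)
    flux = _read_table(flux_path) if flux_path else None

    tables = [abundance, metabolome, covariates] + ([flux] if flux is not None else [])
    common = abundance.index
    for t in tables[1:]:
        common = common.intersection(t.index)
    dropped = sorted(set().union(*(set(t.index) for t in tables)) - set(common))
    if dropped:
        logger.warning("dropping %d sample(s) absent from some table: %s",
                       len(dropped), dropped[:10])
    if len(common) == 0:
        raise FormatError("no common sample ids across the tables")

    abundance = abundance.loc[common]
    sums = abundance.sum(axis=1)
    off = sums[(sums - 1).abs() > 0.01]
    if len(off):
        raise FormatError(
            f"abundance rows must sum to 1 (+-1%); offending sample(s): "
            f"{off.index.tolist()[:5]} with sums {off.round(3).tolist()[:5]}"
        )
    abundance = abundance.div(sums, axis=0)

    st = StudyTables(
        abundance=abundance,
        metabolome=metabolome.loc[common],
        covariates=covariates.loc[common],
        flux=flux.loc[common] if flux is not None else None,
    )
    st.validate()
    return st


def write_table(df: pd.DataFrame, path: str | Path, config: RunConfig | None = None,
                index_label: str = "sample") -> None:
    """Write a CSV with an optional config-hash header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# fluxpattern config_hash={config.config_hash} seed={config.seed}\n")
        df.to_csv(fh, index_label=index_label)


def read_config_hash(path: str | Path) -> str | None:
    """Config hash recorded in a table's header comment, if any."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "config_hash=" in first:
        return first.split("config_hash=")[1].split()[0]
    return None


# ---------------------------------------------------------------------------
# Simulated cohorts
# ---------------------------------------------------------------------------

def cohort_to_tables(
    cohort: SEMCohort, params: SEMParameters, detection_quantile: float = 0.05
) -> StudyTables:
    """View a simulated cohort as StudyTables (host factors as covariates).

    The structural concentrations live on the log scale (the in vivo screens
    regress log concentrations), so the metabolome table is ``exp(C)`` —
    right-skewed and positive — with the lowest ``detection_quantile`` of
    each metabolite censored to 0 to emulate below-detection-limit zeros.
    """
    idx = pd.Index([f"s{i:05d}" for i in range(cohort.n)], name="sample")
    species = [f"sp{l + 1:03d}" for l in range(params.L)]
    metabolites = [f"met{j + 1:02d}" for j in range(params.J)]
    host = [f"h{k + 1}" for k in range(params.K)]
    conc = np.exp(cohort.C)
    if detection_quantile > 0:
        lod = np.quantile(conc, detection_quantile, axis=0)
        conc = np.where(conc < lod, 0.0, conc)
    return StudyTables(
        abundance=pd.DataFrame(cohort.A, index=idx, columns=species),
        metabolome=pd.DataFrame(conc, index=idx, columns=metabolites),
        covariates=pd.DataFrame(cohort.H, index=idx, columns=host),
        flux=pd.DataFrame(cohort.F, index=idx, columns=metabolites),
    )


def write_cohort(
    cohort: SEMCohort,
    params: SEMParameters,
    outdir: str | Path,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Write a simulated cohort as the four study CSVs plus a truth sidecar.

    Concentrations are written on the natural (exponentiated, zero-censored)
    scale; the truth JSON records the generating matrices, the realized
    (post-repair) host->abundance coefficients and the simplex-repair scale,
    for parameter-recovery tests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = cohort_to_tables(cohort, params)
    paths = {}
    for name, df in (("abundance", tables.abundance),
                     ("metabolome", tables.metabolome),
                     ("flux", tables.flux),
                     ("covariates", tables.covariates)):
        paths[name] = outdir / f"{name}.csv"
        write_table(df, paths[name], config)
    truth = params.to_dict()
    truth["host_effect_scale_used"] = cohort.host_effect_scale_used
    truth["repair_fraction"] = cohort.repair_fraction
    truth["realized_B_ah"] = np.asarray(cohort.realized_B_ah).tolist()
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths


# ---------------------------------------------------------------------------
# Reconstructions
# ---------------------------------------------------------------------------

def reconstruction_to_dict(recon: Reconstruction) -> dict:
    return {
        "id": recon.id,
        "metabolites": [{"id": m.id, "compartment": m.compartment}
                        for m in recon.metabolites],
        "reactions": [{"id": r.id, "stoichiometry": r.stoichiometry,
                       "lower": r.lower, "upper": r.upper}
                      for r in recon.reactions],
        "biomass_reaction": recon.biomass_reaction,
        "exchange_reactions": list(recon.exchange_reactions),
    }


def write_reconstruction(recon: Reconstruction, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(reconstruction_to_dict(recon), fh, indent=1)


def read_reconstruction(path: str | Path) -> Reconstruction:
    """Load and validate a reconstruction from its JSON schema."""
    with open(path) as fh:
        raw = json.load(fh)
    missing = [k for k in _RECON_REQUIRED if k not in raw]
    if missing:
        raise ValidationError(f"{path}: missing required fields {missing}")
    recon = Reconstruction(
        id=raw["id"],
        metabolites=[Metabolite(m["id"], m.get("compartment", "c"))
                     for m in raw["metabolites"]],
        reactions=[Reaction(r["id"], dict(r["stoichiometry"]),
                            float(r.get("lower", 0.0)), float(r.get("upper", 1000.0)))
                   for r in raw["reactions"]],
        biomass_reaction=raw["biomass_reaction"],
        exchange_reactions=list(raw.get("exchange_reactions", [])),
    )
    recon.validate()
    return recon


def read_reconstruction_sbml(path: str | Path) -> Reconstruction:
    """Import an SBML (fbc) model through cobra and map it onto the toy schema.

    Only species, reactions, bounds and the objective (biomass) are used;
    boundary metabolites are skipped.  Exchange reactions are cobra's
    boundary reactions of exchange type.
    """
    try:
        from cobra.io import read_sbml_model
    except ImportError as exc:  # pragma: no cover - cobra is an extra
        raise ValidationError("SBML import requires the 'cobra' package") from exc

    model = read_sbml_model(str(path))
    mets = [Metabolite(m.id, "e" if m.compartment in ("e", "e0") else "c")
            for m in model.metabolites]
    reactions = []
    for r in model.reactions:
        stoich = {m.id: float(coef) for m, coef in r.metabolites.items()}
        reactions.append(Reaction(r.id, stoich, float(r.lower_bound),
                                  float(r.upper_bound)))
    biomass = None
    for r in model.reactions:
        if r.objective_coefficient:
            biomass = r.id
            break
    if biomass is None:
        candidates = [r.id for r in model.reactions if "biomass" in r.id.lower()]
        if not candidates:
            raise ValidationError(f"{path}: no objective or biomass reaction found")
        biomass = candidates[0]
    exchanges = [r.id for r in model.exchanges]
    recon = Reconstruction(
        id=model.id or Path(path).stem,
        metabolites=mets,
        reactions=reactions,
        biomass_reaction=biomass,
        exchange_reactions=exchanges,
    )
    recon.validate()
    return recon


def read_diet(path: str | Path) -> dict[str, float]:
    """Diet TSV/CSV: metabolite id, supply (nonnegative, mmol/person/day)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: diet file needs (metabolite, supply) columns")
    met_col, supply_col = df.columns[:2]
    diet = {}
    for _, row in df.iterrows():
        supply = float(row[supply_col])
        if supply < 0:
            raise FormatError(f"{path}: negative supply for {row[met_col]!r}")
        diet[str(row[met_col])] = supply
    return diet
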