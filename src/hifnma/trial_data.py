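"""Aggregate trial contrasts: data model, I/O, and scale algebra.

The unit of evidence is one two-arm trial's relative effect (treatment vs
comparator) on one outcome, reported either as a point estimate with a 95%
confidence interval on the reporting scale (g/dL, SF-36 points, or a hazard
ratio) or with a standard error on the analysis scale.  Continuous outcomes
are analysed on the identity scale; time-to-event outcomes as log hazard
ratios, exponentiated for reporting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("hifnma")

#: two-sided 97.5% standard-normal quantile, fixed at six decimals so that
#: CI -> SE -> CI round trips are bit-stable across the package.
Z975 = 1.959964

IDENTITY = "identity"
LOG = "log"
EXPONENTIATED = "exponentiated"

#: CSV schema for evidence-base files (population_tags semicolon-separated).
CONTRAST_COLUMNS = [
    "trial_id",
    "treatment",
    "comparator",
    "outcome_id",
    "estimate",
    "ci_lower",
    "ci_upper",
    "se",
    "population_tags",
    "n",
]

CONFIG_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Input table or config file does not match the expected schema."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


@dataclass(frozen=True)
class OutcomeSpec:
    """Definition of one outcome: its label, scales, and units.

    ``analysis_scale`` is the scale the likelihood sees (identity for mean
    changes, log for hazard ratios); ``reporting_scale`` maps posterior
    summaries back for presentation (exponentiated for HRs).
    """

    outcome_id: str
    analysis_scale: str = IDENTITY
    reporting_scale: str = IDENTITY
    units: str = ""

    def __post_init__(self) -> None:
        if self.analysis_scale not in (IDENTITY, LOG):
            raise ValidationError(f"unknown analysis_scale {self.analysis_scale!r}")
        if self.reporting_scale not in (IDENTITY, EXPONENTIATED):
            raise ValidationError(f"unknown reporting_scale {self.reporting_scale!r}")
        # ratio outcomes must be log/exponentiated, continuous identity/identity
        if (self.analysis_scale == LOG) != (self.reporting_scale == EXPONENTIATED):
            raise ValidationError(
                f"outcome {self.outcome_id!r}: analysis_scale {self.analysis_scale!r} "
                f"is inconsistent with reporting_scale {self.reporting_scale!r}"
            )


#: Outcomes of the HIF-PHI evidence base: haemoglobin change from baseline,
#: time to first MACE, and SF-36 Vitality change from baseline.
DEFAULT_OUTCOMES: dict[str, OutcomeSpec] = {
    "hgb_cfb": OutcomeSpec("hgb_cfb", IDENTITY, IDENTITY, "g/dL"),
    "mace": OutcomeSpec("mace", LOG, EXPONENTIATED, "HR"),
    "sf36_vitality": OutcomeSpec("sf36_vitality", IDENTITY, IDENTITY, "points"),
}


@dataclass(frozen=True)
class TrialContrast:
    """One trial's aggregate effect of ``treatment`` vs ``comparator``.

    ``estimate`` and the CI bounds live on the reporting scale; ``se`` on the
    analysis scale.  At least one of (CI pair, se) must be present.
    """

    trial_id: str
    treatment: str
    comparator: str
    outcome_id: str
    estimate: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    se: float | None = None
    population_tags: frozenset[str] = frozenset()
    n: int | None = None

    def __post_init__(self) -> None:
        if self.treatment == self.comparator:
            raise ValidationError(
                f"trial {self.trial_id!r}: treatment equals comparator "
                f"({self.treatment!r})"
            )
        has_ci = self.ci_lower is not None and self.ci_upper is not None
        if not has_ci and self.se is None:
            raise ValidationError(
                f"trial {self.trial_id!r}: needs a CI pair or a standard error"
            )
        if (self.ci_lower is None) != (self.ci_upper is None):
            raise ValidationError(
                f"trial {self.trial_id!r}: CI bounds must be given together"
            )
        if has_ci and not (self.ci_lower < self.estimate < self.ci_upper):
            raise ValidationError(
                f"trial {self.trial_id!r}: CI ({self.ci_lower}, {self.ci_upper}) "
                f"must strictly bracket the estimate {self.estimate}"
            )
        if self.se is not None and not self.se > 0:
            raise ValidationError(f"trial {self.trial_id!r}: se must be positive")
        if self.n is not None and self.n <= 0:
            raise ValidationError(f"trial {self.trial_id!r}: n must be positive")
        object.__setattr__(self, "population_tags", frozenset(self.population_tags))

    def has_ci(self) -> bool:
        return self.ci_lower is not None and self.ci_upper is not None


@dataclass(frozen=True)
class AnalysisSet:
    """Population subset plus comparator-node merging for one analysis.

    ``include_tags`` are required population tags (empty = keep everything),
    e.g. {"esa_nonuser"} for the non-dialysis ESA non-user analysis or
    {"prevalent"} for the prevalent-dialysis analysis.  ``node_merge_map``
    rewrites raw arm labels, typically collapsing darbepoetin / epoetin /
    rHEpo onto a single "ESA" reference node.
    """

    set_id: str
    description: str = ""
    include_tags: frozenset[str] = frozenset()
    node_merge_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "include_tags", frozenset(self.include_tags))
        merge = dict(self.node_merge_map)
        for src, dst in merge.items():
            # merge targets must be terminal, else relabelling is not idempotent
            if dst in merge and merge[dst] != dst:
                raise ValidationError(
                    f"analysis set {self.set_id!r}: merge target {dst!r} is itself remapped"
                )
        object.__setattr__(self, "node_merge_map", merge)

    def includes(self, contrast: TrialContrast) -> bool:
        return self.include_tags <= contrast.population_tags


# ---------------------------------------------------------------------------
# scale algebra
# ---------------------------------------------------------------------------


def ci_to_se(ci_lower: float, ci_upper: float, scale: str) -> float:
    """SE on the analysis scale from a 95% CI on the reporting scale.

    Returns ``(u - l) / (2 * 1.959964)`` after mapping the bounds to the
    analysis scale (natural log for ratio outcomes).
    """
    if not ci_lower < ci_upper:
        raise ValidationError(
            f"degenerate interval: ci_lower {ci_lower} must be < ci_upper {ci_upper}"
        )
    if scale == LOG:
        if ci_lower <= 0 or ci_upper <= 0:
            raise ValidationError(
                f"log-scale CI bounds must be positive, got ({ci_lower}, {ci_upper})"
            )
        lo, hi = math.log(ci_lower), math.log(ci_upper)
    elif scale == IDENTITY:
        lo, hi = ci_lower, ci_upper
    else:
        raise ValidationError(f"unknown scale {scale!r}")
    return (hi - lo) / (2.0 * Z975)


def se_to_ci(se: float, center: float, scale: str) -> tuple[float, float]:
    """Inverse of :func:`ci_to_se`: symmetric 95% CI around ``center``.

    ``center`` is on the analysis scale; the returned bounds are on the
    reporting scale (exponentiated for log outcomes).
    """
    if not se > 0:
        raise ValidationError("se must be positive")
    lo, hi = center - Z975 * se, center + Z975 * se
    if scale == LOG:
        return math.exp(lo), math.exp(hi)
    if scale == IDENTITY:
        return lo, hi
    raise ValidationError(f"unknown scale {scale!r}")


def to_reporting_scale(value: float, spec: OutcomeSpec) -> float:
    """Map an analysis-scale quantity to the outcome's reporting scale.

    Single boundary function shared by the MCMC engine and the closed-form
    oracle so exp/log conventions cannot diverge.
    """
    if spec.reporting_scale == EXPONENTIATED:
        return math.exp(value)
    return value


def to_analysis_scale(c: TrialContrast, spec: OutcomeSpec) -> tuple[float, float]:
    """Observed contrast ``(y, se)`` on the analysis scale.

    Identity outcomes pass the estimate through; ratio outcomes take its
    natural log.  When a CI is present it defines the SE (the printed inputs
    are CIs); a redundant ``se`` is cross-checked against the CI-derived one.
    """
    if c.outcome_id != spec.outcome_id:
        raise ValidationError(
            f"contrast outcome {c.outcome_id!r} does not match spec {spec.outcome_id!r}"
        )
    if spec.analysis_scale == LOG:
        if c.estimate <= 0:
            raise ValidationError(
                f"trial {c.trial_id!r}: log-scale estimate must be positive"
            )
        y = math.log(c.estimate)
    else:
        y = c.estimate

    if c.has_ci():
        se = ci_to_se(c.ci_lower, c.ci_upper, spec.analysis_scale)
        if c.se is not None and not math.isclose(
            se, c.se, rel_tol=1e-6, abs_tol=1e-6
        ):
            raise ValidationError(
                f"trial {c.trial_id!r}: supplied se {c.se} inconsistent with "
                f"CI-derived se {se:.8g}"
            )
    else:
        se = c.se
    return y, se


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _parse_tags(raw: object) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return frozenset()
    return frozenset(t.strip() for t in str(raw).split(";") if t.strip())


def read_contrasts(
    path: str | Path, outcome_catalog: Mapping[str, OutcomeSpec] | None = None
) -> list[TrialContrast]:
    """Read an evidence-base CSV into validated :class:`TrialContrast` rows.

    Rows violating invariants raise, citing the offending row; they are never
    silently dropped.
    """
    catalog = DEFAULT_OUTCOMES if outcome_catalog is None else outcome_catalog
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    missing = [c for c in CONTRAST_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    if frame.empty:
        logger.warning("%s: no contrast rows (header only)", path)
        return []

    contrasts: list[TrialContrast] = []
    for idx, row in frame.iterrows():
        outcome_id = str(row["outcome_id"])
        if outcome_id not in catalog:
            raise SchemaError(
                f"{path} row {idx}: unknown outcome_id {outcome_id!r} "
                f"(catalog: {sorted(catalog)})"
            )
        spec = catalog[outcome_id]

        def _opt(col: str) -> float | None:
            v = row[col]
            return None if pd.isna(v) else float(v)

        try:
            c = TrialContrast(
                trial_id=str(row["trial_id"]),
                treatment=str(row["treatment"]),
                comparator=str(row["comparator"]),
                outcome_id=outcome_id,
                estimate=float(row["estimate"]),
                ci_lower=_opt("ci_lower"),
                ci_upper=_opt("ci_upper"),
                se=_opt("se"),
                population_tags=_parse_tags(row["population_tags"]),
                n=None if pd.isna(row["n"]) else int(row["n"]),
            )
            if spec.analysis_scale == LOG:
                for bound in ("estimate", "ci_lower", "ci_upper"):
                    v = getattr(c, bound)
                    if v is not None and v <= 0:
                        raise ValidationError(
                            f"log-scale outcome requires positive {bound}, got {v}"
                        )
            to_analysis_scale(c, spec)  # exercises CI/SE consistency
        except ValidationError as exc:
            raise ValidationError(f"{path} row {idx}: {exc}") from exc
        contrasts.append(c)
    return contrasts


def write_contrasts(contrasts: Sequence[TrialContrast], path: str | Path) -> None:
    """Write contrasts in the evidence-base CSV schema."""
    rows = []
    for c in contrasts:
        rows.append(
            {
                "trial_id": c.trial_id,
                "treatment": c.treatment,
                "comparator": c.comparator,
                "outcome_id": c.outcome_id,
                "estimate": c.estimate,
                "ci_lower": c.ci_lower,
                "ci_upper": c.ci_upper,
                "se": c.se,
                "population_tags": ";".join(sorted(c.population_tags)),
                "n": c.n,
            }
        )
    pd.DataFrame(rows, columns=CONTRAST_COLUMNS).to_csv(path, index=False)


def filter_analysis_set(
    contrasts: Iterable[TrialContrast], aset: AnalysisSet
) -> list[TrialContrast]:
    """Apply an analysis set: tag filter, then node-label merging.

    Preserves input order; idempotent because the merge map is terminal.
    """
    merge = aset.node_merge_map
    out: list[TrialContrast] = []
    for c in contrasts:
        if not aset.includes(c):
            continue
        t = merge.get(c.treatment, c.treatment)
        k = merge.get(c.comparator, c.comparator)
        if (t, k) != (c.treatment, c.comparator):
            c = TrialContrast(
                trial_id=c.trial_id,
                treatment=t,
                comparator=k,
                outcome_id=c.outcome_id,
                estimate=c.estimate,
                ci_lower=c.ci_lower,
                ci_upper=c.ci_upper,
                se=c.se,
                population_tags=c.population_tags,
                n=c.n,
            )
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# config files (outcome catalogs, analysis sets)
# ---------------------------------------------------------------------------


def _check_schema_version(doc: Mapping, path: Path) -> None:
    version = doc.get("schema_version")
    if version != CONFIG_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema_version must be {CONFIG_SCHEMA_VERSION}, got {version!r}"
        )


def load_outcome_catalog(path: str | Path) -> dict[str, OutcomeSpec]:
    """Load an outcome catalog from a YAML config with a schema version."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    _check_schema_version(doc, path)
    catalog = {}
    for oid, entry in doc.get("outcomes", {}).items():
        catalog[oid] = OutcomeSpec(
            outcome_id=oid,
            analysis_scale=entry.get("analysis_scale", IDENTITY),
            reporting_scale=entry.get("reporting_scale", IDENTITY),
            units=entry.get("units", ""),
        )
    return catalog


def load_analysis_sets(path: str | Path) -> dict[str, AnalysisSet]:
    """Load analysis sets (tag filters + node merge maps) from YAML."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    _check_schema_version(doc, path)
    sets = {}
    for sid, entry in doc.get("analysis_sets", {}).items():
        sets[sid] = AnalysisSet(
            set_id=sid,
            description=entry.get("description", ""),
            include_tags=frozenset(entry.get("include_tags", [])),
            node_merge_map=entry.get("node_merge_map", {}),
        )
    return sets
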