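"""Typed, validated model inputs for the activity-programme cost-utility model.

Every scalar that enters the Markov model is held as a :class:`Param` —
a base-case value plus, where a sensitivity range is defined, lower/upper
limits and the distribution family used in probabilistic sensitivity
analysis.  The bundled ``base_case.yaml`` document is the canonical source
of all base-case inputs; :func:`load_parameters` validates it strictly
(unknown keys are an error, so typos in sensitivity specifications fail
loudly rather than silently falling back to defaults).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping, Optional, Sequence

import yaml

__all__ = [
    "Param",
    "ActivityDistribution",
    "AgeBand",
    "AgeBandTable",
    "DiseaseRR",
    "RelativeRiskSet",
    "CauseRR",
    "PostEventMortalityRR",
    "UtilityParams",
    "DiseaseParams",
    "StageCostComponents",
    "ProgrammeParams",
    "EconomicSettings",
    "ModelParameters",
    "ParameterError",
    "load_parameters",
    "load_default_parameters",
    "serialize_parameters",
    "mental_health_gain",
    "iter_scalar_params",
    "get_param",
    "set_value",
]

DISEASES = ("chd", "stroke", "diabetes")
LEVELS = ("low", "moderate", "high")

KNOWN_DISTRIBUTIONS = {"beta", "gamma", "lognormal", "normal", "uniform", "dirichlet"}


class ParameterError(ValueError):
    """Raised when a configuration document fails validation."""


@dataclass(frozen=True)
class Param:
    """A scalar input: base-case value and optional sensitivity range."""

    value: float
    lower: Optional[float] = None
    upper: Optional[float] = None
    dist: Optional[str] = None

    def __post_init__(self) -> None:
        if self.dist is not None and self.dist not in KNOWN_DISTRIBUTIONS:
            raise ParameterError(f"unknown distribution family {self.dist!r}")
        if self.lower is not None and self.upper is not None:
            if not (self.lower <= self.upper):
                raise ParameterError(
                    f"lower bound {self.lower} exceeds upper bound {self.upper}"
                )
            if not (self.lower <= self.value <= self.upper):
                raise ParameterError(
                    f"value {self.value} outside [{self.lower}, {self.upper}]"
                )

    @property
    def has_range(self) -> bool:
        return self.lower is not None and self.upper is not None and self.dist is not None


@dataclass(frozen=True)
class ActivityDistribution:
    """Proportions of a cohort in the low/moderate/high activity levels."""

    low: Param
    moderate: Param
    high: Param

    def __post_init__(self) -> None:
        total = self.low.value + self.moderate.value + self.high.value
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"activity fractions sum to {total}, not 1")
        for p in (self.low, self.moderate, self.high):
            if not (0.0 <= p.value <= 1.0):
                raise ParameterError(f"activity fraction {p.value} outside [0, 1]")

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.low.value, self.moderate.value, self.high.value)

    def with_fraction(self, level: str, value: float) -> "ActivityDistribution":
        """Set one fraction for a one-way sweep.

        Varying the moderate or high share trades mass against the *low*
        (inactive) pool, holding the other active level fixed — the natural
        reading of "what if fewer/more people were already active".  Varying
        the low share renormalizes moderate and high proportionally.
        """
        if level not in LEVELS:
            raise ParameterError(f"unknown activity level {level!r}")
        if not (0.0 <= value < 1.0):
            raise ParameterError(f"fraction {value} outside [0, 1)")
        old = dict(zip(LEVELS, self.fractions))
        new = dict(old)
        new[level] = value
        if level == "low":
            rest = old["moderate"] + old["high"]
            if rest <= 0.0:
                raise ParameterError("cannot renormalize: active levels have zero mass")
            scale = (1.0 - value) / rest
            new["moderate"] = old["moderate"] * scale
            new["high"] = old["high"] * scale
        else:
            new["low"] = old["low"] - (value - old[level])
            if new["low"] < 0.0:
                raise ParameterError(
                    f"setting {level} to {value} exhausts the low-activity pool")
        return self.with_fractions(new["low"], new["moderate"], new["high"])

    def with_fractions(self, low: float, moderate: float, high: float) -> "ActivityDistribution":
        return ActivityDistribution(
            low=_with_value(self.low, low),
            moderate=_with_value(self.moderate, moderate),
            high=_with_value(self.high, high),
        )


@dataclass(frozen=True)
class AgeBand:
    age_lo: int
    age_hi: int
    param: Param


@dataclass(frozen=True)
class AgeBandTable:
    """Ordered, non-overlapping integer age bands; lookups clamp at both ends."""

    bands: tuple[AgeBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ParameterError("age-band table is empty")
        prev_hi = None
        for band in self.bands:
            if band.age_lo > band.age_hi:
                raise ParameterError(f"band {band.age_lo}-{band.age_hi} is inverted")
            if prev_hi is not None and band.age_lo <= prev_hi:
                raise ParameterError("age bands overlap or are out of order")
            prev_hi = band.age_hi

    def value(self, age: int) -> float:
        return self.band(age).param.value

    def band(self, age: int) -> AgeBand:
        if age <= self.bands[0].age_hi:
            return self.bands[0]
        for band in self.bands:
            if band.age_lo <= age <= band.age_hi:
                return band
        return self.bands[-1]

    def band_index(self, age: int) -> int:
        band = self.band(age)
        return self.bands.index(band)


@dataclass(frozen=True)
class DiseaseRR:
    """Incidence risk ratios for moderate/high activity versus low."""

    moderate: Param
    high: Param

    def __post_init__(self) -> None:
        for p in (self.moderate, self.high):
            if p.value <= 0:
                raise ParameterError("relative risk must be positive")

    def factor(self, level: str) -> float:
        if level == "low":
            return 1.0
        return getattr(self, level).value


@dataclass(frozen=True)
class RelativeRiskSet:
    chd: DiseaseRR
    stroke: DiseaseRR
    diabetes: DiseaseRR

    def for_disease(self, disease: str) -> DiseaseRR:
        return getattr(self, disease)


@dataclass(frozen=True)
class CauseRR:
    """Cause-specific background-mortality multipliers after a survived event."""

    cvd: Param
    non_cvd: Param

    def __post_init__(self) -> None:
        for p in (self.cvd, self.non_cvd):
            if p.value < 1.0:
                raise ParameterError("post-event mortality relative risk must be >= 1")


@dataclass(frozen=True)
class PostEventMortalityRR:
    chd: CauseRR
    stroke: CauseRR
    diabetes: CauseRR

    def for_disease(self, disease: str) -> CauseRR:
        return getattr(self, disease)


@dataclass(frozen=True)
class UtilityParams:
    age_bands: AgeBandTable
    chd_first_event: Param
    chd_post_event: Param
    stroke_first_event: Param
    stroke_post_event: Param
    diabetes: Param
    mh_gain_moderate: Param
    mh_gain_high: Param
    per_halfhour_gain: float
    extra_hours_moderate: float
    extra_hours_high: float

    def __post_init__(self) -> None:
        for band in self.age_bands.bands:
            if not (0.0 <= band.param.value <= 1.0):
                raise ParameterError("age utility outside [0, 1]")
        for name in ("chd_first_event", "chd_post_event", "stroke_first_event",
                     "stroke_post_event", "diabetes"):
            v = getattr(self, name).value
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"utility {name} outside [0, 1]")
        for name in ("mh_gain_moderate", "mh_gain_high"):
            if getattr(self, name).value < 0:
                raise ParameterError(f"{name} must be >= 0")

    def mh_gain(self, level: str) -> float:
        if level == "low":
            return 0.0
        if level == "moderate":
            return self.mh_gain_moderate.value
        if level == "high":
            return self.mh_gain_high.value
        raise ParameterError(f"unknown activity level {level!r}")


@dataclass(frozen=True)
class DiseaseParams:
    incidence: AgeBandTable
    fatal_fraction: Optional[AgeBandTable]
    first_event_cost: Optional[Param]
    annual_state_cost: Param

    def __post_init__(self) -> None:
        for band in self.incidence.bands:
            if not (0.0 <= band.param.value <= 1.0):
                raise ParameterError("incidence outside [0, 1]")
        if self.fatal_fraction is not None:
            for band in self.fatal_fraction.bands:
                if not (0.0 <= band.param.value <= 1.0):
                    raise ParameterError("fatal fraction outside [0, 1]")
        if self.first_event_cost is not None and self.first_event_cost.value < 0:
            raise ParameterError("first-event cost must be >= 0")
        if self.annual_state_cost.value < 0:
            raise ParameterError("annual state cost must be >= 0")


@dataclass(frozen=True)
class StageCostComponents:
    induction: float
    membership_per_month: float
    membership_months: tuple[int, ...]
    follow_up: float
    communication: float

    @property
    def total_per_completer(self) -> float:
        return (self.induction
                + self.membership_per_month * len(self.membership_months)
                + self.follow_up + self.communication)


DROPOUT_STAGES = ("did_not_start", "month_1", "month_2", "month_3", "month_4")


@dataclass(frozen=True)
class ProgrammeParams:
    n_recruited: int
    n_completers: int
    dropout_counts: tuple[int, ...]  # ordered per DROPOUT_STAGES
    completion: Param
    general_cost_per_recruit: Param
    sports_cost_per_completer: Param
    sports_cost_per_noncompleter: Param
    stage_cost_components: StageCostComponents
    duration_of_effect_months: Param
    baseline_activity: ActivityDistribution
    followup_activity: ActivityDistribution

    def __post_init__(self) -> None:
        if self.n_completers + sum(self.dropout_counts) != self.n_recruited:
            raise ParameterError(
                "completers plus dropouts do not account for every recruit")
        if any(c < 0 for c in self.dropout_counts):
            raise ParameterError("dropout counts must be >= 0")


@dataclass(frozen=True)
class EconomicSettings:
    annual_discount_rate: float
    cycle_length_months: int
    starting_age: Param
    max_age: int
    wtp_threshold: float

    def __post_init__(self) -> None:
        if self.annual_discount_rate < 0:
            raise ParameterError("discount rate must be >= 0")
        if self.starting_age.value >= self.max_age:
            raise ParameterError("starting age must be below the maximum age")


@dataclass(frozen=True)
class ModelParameters:
    settings: EconomicSettings
    programme: ProgrammeParams
    relative_risks: RelativeRiskSet
    mortality_rrs: PostEventMortalityRR
    utilities: UtilityParams
    chd: DiseaseParams
    stroke: DiseaseParams
    diabetes: DiseaseParams

    def disease(self, name: str) -> DiseaseParams:
        if name not in DISEASES:
            raise ParameterError(f"unknown disease {name!r}")
        return getattr(self, name)


# --------------------------------------------------------------------------
# loading and validation

def _require_mapping(node, context: str) -> Mapping:
    if not isinstance(node, Mapping):
        raise ParameterError(f"{context}: expected a mapping")
    return node


def _check_keys(node: Mapping, allowed: set[str], context: str) -> None:
    unknown = set(node) - allowed
    if unknown:
        raise ParameterError(f"{context}: unknown key(s) {sorted(unknown)}")
    missing = allowed - set(node)
    if missing:
        raise ParameterError(f"{context}: missing key(s) {sorted(missing)}")


def _parse_param(node, context: str, required_range: bool = False) -> Param:
    if isinstance(node, (int, float)) and not isinstance(node, bool):
        if required_range:
            raise ParameterError(f"{context}: a sensitivity range is required")
        return Param(value=float(node))
    node = _require_mapping(node, context)
    unknown = set(node) - {"value", "lower", "upper", "dist"}
    if unknown:
        raise ParameterError(f"{context}: unknown key(s) {sorted(unknown)}")
    if "value" not in node:
        raise ParameterError(f"{context}: missing 'value'")
    try:
        return Param(
            value=float(node["value"]),
            lower=None if node.get("lower") is None else float(node["lower"]),
            upper=None if node.get("upper") is None else float(node["upper"]),
            dist=node.get("dist"),
        )
    except ParameterError as exc:
        raise ParameterError(f"{context}: {exc}") from None


def _parse_band_table(node, context: str) -> AgeBandTable:
    if not isinstance(node, Sequence):
        raise ParameterError(f"{context}: expected a list of bands")
    bands = []
    for i, entry in enumerate(node):
        entry = _require_mapping(entry, f"{context}[{i}]")
        unknown = set(entry) - {"age_lo", "age_hi", "value", "lower", "upper", "dist"}
        if unknown:
            raise ParameterError(f"{context}[{i}]: unknown key(s) {sorted(unknown)}")
        param = _parse_param(
            {k: entry[k] for k in ("value", "lower", "upper", "dist") if k in entry},
            f"{context}[{i}]",
        )
        bands.append(AgeBand(int(entry["age_lo"]), int(entry["age_hi"]), param))
    try:
        return AgeBandTable(tuple(bands))
    except ParameterError as exc:
        raise ParameterError(f"{context}: {exc}") from None


def _parse_activity(node, context: str) -> ActivityDistribution:
    node = _require_mapping(node, context)
    _check_keys(node, {"low", "moderate", "high"}, context)
    parts = {lv: _parse_param(node[lv], f"{context}.{lv}") for lv in LEVELS}
    total = sum(p.value for p in parts.values())
    if abs(total - 1.0) > 5e-3:
        raise ParameterError(f"{context}: activity fractions sum to {total}, not 1")
    # tolerate rounded published percentages (e.g. summing to 99.9 %):
    # renormalize proportionally so the invariant holds exactly
    parts = {lv: dataclasses.replace(p, value=p.value / total)
             for lv, p in parts.items()}
    try:
        return ActivityDistribution(**parts)
    except ParameterError as exc:
        raise ParameterError(f"{context}: {exc}") from None


def load_parameters(config_text: str) -> ModelParameters:
    """Parse and validate a configuration document into :class:`ModelParameters`.

    Raises :class:`ParameterError` naming the offending key on any missing
    key, unknown key, bound violation or unknown distribution family.
    """
    doc = yaml.safe_load(config_text)
    doc = _require_mapping(doc, "document")
    _check_keys(doc, {"settings", "programme", "relative_risks", "mortality_rrs",
                      "utilities", "diseases"}, "document")

    s = _require_mapping(doc["settings"], "settings")
    _check_keys(s, {"annual_discount_rate", "cycle_length_months", "starting_age",
                    "max_age", "wtp_threshold"}, "settings")
    settings = EconomicSettings(
        annual_discount_rate=float(s["annual_discount_rate"]),
        cycle_length_months=int(s["cycle_length_months"]),
        starting_age=_parse_param(s["starting_age"], "settings.starting_age"),
        max_age=int(s["max_age"]),
        wtp_threshold=float(s["wtp_threshold"]),
    )

    pr = _require_mapping(doc["programme"], "programme")
    _check_keys(pr, {"n_recruited", "n_completers", "dropout_counts", "completion",
                     "general_cost_per_recruit", "sports_cost_per_completer",
                     "sports_cost_per_noncompleter", "stage_cost_components",
                     "duration_of_effect_months", "baseline_activity",
                     "followup_activity"}, "programme")
    dc = _require_mapping(pr["dropout_counts"], "programme.dropout_counts")
    _check_keys(dc, set(DROPOUT_STAGES), "programme.dropout_counts")
    n_recruited = int(pr["n_recruited"])
    n_completers = int(pr["n_completers"])
    comp_node = _require_mapping(pr["completion"], "programme.completion")
    _check_keys(comp_node, {"lower", "upper", "dist"}, "programme.completion")
    completion = Param(
        value=n_completers / n_recruited,
        lower=float(comp_node["lower"]),
        upper=float(comp_node["upper"]),
        dist=comp_node["dist"],
    )
    scc = _require_mapping(pr["stage_cost_components"], "programme.stage_cost_components")
    _check_keys(scc, {"induction", "membership_per_month", "membership_months",
                      "follow_up", "communication"}, "programme.stage_cost_components")
    programme = ProgrammeParams(
        n_recruited=n_recruited,
        n_completers=n_completers,
        dropout_counts=tuple(int(dc[k]) for k in DROPOUT_STAGES),
        completion=completion,
        general_cost_per_recruit=_parse_param(
            pr["general_cost_per_recruit"], "programme.general_cost_per_recruit"),
        sports_cost_per_completer=_parse_param(
            pr["sports_cost_per_completer"], "programme.sports_cost_per_completer"),
        sports_cost_per_noncompleter=_parse_param(
            pr["sports_cost_per_noncompleter"], "programme.sports_cost_per_noncompleter"),
        stage_cost_components=StageCostComponents(
            induction=float(scc["induction"]),
            membership_per_month=float(scc["membership_per_month"]),
            membership_months=tuple(int(m) for m in scc["membership_months"]),
            follow_up=float(scc["follow_up"]),
            communication=float(scc["communication"]),
        ),
        duration_of_effect_months=_parse_param(
            pr["duration_of_effect_months"], "programme.duration_of_effect_months"),
        baseline_activity=_parse_activity(pr["baseline_activity"],
                                          "programme.baseline_activity"),
        followup_activity=_parse_activity(pr["followup_activity"],
                                          "programme.followup_activity"),
    )

    rr = _require_mapping(doc["relative_risks"], "relative_risks")
    _check_keys(rr, set(DISEASES), "relative_risks")
    rr_sets = {}
    for d in DISEASES:
        node = _require_mapping(rr[d], f"relative_risks.{d}")
        _check_keys(node, {"moderate", "high"}, f"relative_risks.{d}")
        rr_sets[d] = DiseaseRR(
            moderate=_parse_param(node["moderate"], f"relative_risks.{d}.moderate"),
            high=_parse_param(node["high"], f"relative_risks.{d}.high"),
        )
    relative_risks = RelativeRiskSet(**rr_sets)

    mr = _require_mapping(doc["mortality_rrs"], "mortality_rrs")
    _check_keys(mr, set(DISEASES), "mortality_rrs")
    mr_sets = {}
    for d in DISEASES:
        node = _require_mapping(mr[d], f"mortality_rrs.{d}")
        _check_keys(node, {"cvd", "non_cvd"}, f"mortality_rrs.{d}")
        mr_sets[d] = CauseRR(
            cvd=_parse_param(node["cvd"], f"mortality_rrs.{d}.cvd"),
            non_cvd=_parse_param(node["non_cvd"], f"mortality_rrs.{d}.non_cvd"),
        )
    mortality_rrs = PostEventMortalityRR(**mr_sets)

    ut = _require_mapping(doc["utilities"], "utilities")
    _check_keys(ut, {"age_bands", "chd_first_event", "chd_post_event",
                     "stroke_first_event", "stroke_post_event", "diabetes",
                     "mh_gain_moderate", "mh_gain_high", "per_halfhour_gain",
                     "extra_hours_moderate", "extra_hours_high"}, "utilities")
    utilities = UtilityParams(
        age_bands=_parse_band_table(ut["age_bands"], "utilities.age_bands"),
        chd_first_event=_parse_param(ut["chd_first_event"], "utilities.chd_first_event"),
        chd_post_event=_parse_param(ut["chd_post_event"], "utilities.chd_post_event"),
        stroke_first_event=_parse_param(ut["stroke_first_event"],
                                        "utilities.stroke_first_event"),
        stroke_post_event=_parse_param(ut["stroke_post_event"],
                                       "utilities.stroke_post_event"),
        diabetes=_parse_param(ut["diabetes"], "utilities.diabetes"),
        mh_gain_moderate=_parse_param(ut["mh_gain_moderate"], "utilities.mh_gain_moderate"),
        mh_gain_high=_parse_param(ut["mh_gain_high"], "utilities.mh_gain_high"),
        per_halfhour_gain=float(ut["per_halfhour_gain"]),
        extra_hours_moderate=float(ut["extra_hours_moderate"]),
        extra_hours_high=float(ut["extra_hours_high"]),
    )

    ds = _require_mapping(doc["diseases"], "diseases")
    _check_keys(ds, set(DISEASES), "diseases")
    disease_params = {}
    for d in DISEASES:
        node = _require_mapping(ds[d], f"diseases.{d}")
        allowed = {"incidence", "annual_state_cost"}
        if d != "diabetes":
            allowed |= {"fatal_fraction", "first_event_cost"}
        _check_keys(node, allowed, f"diseases.{d}")
        disease_params[d] = DiseaseParams(
            incidence=_parse_band_table(node["incidence"], f"diseases.{d}.incidence"),
            fatal_fraction=(
                _parse_band_table(node["fatal_fraction"], f"diseases.{d}.fatal_fraction")
                if d != "diabetes" else None),
            first_event_cost=(
                _parse_param(node["first_event_cost"], f"diseases.{d}.first_event_cost")
                if d != "diabetes" else None),
            annual_state_cost=_parse_param(node["annual_state_cost"],
                                           f"diseases.{d}.annual_state_cost"),
        )

    return ModelParameters(
        settings=settings,
        programme=programme,
        relative_risks=relative_risks,
        mortality_rrs=mortality_rrs,
        utilities=utilities,
        chd=disease_params["chd"],
        stroke=disease_params["stroke"],
        diabetes=disease_params["diabetes"],
    )


def load_default_parameters() -> ModelParameters:
    """Load the bundled base-case configuration."""
    text = resources.files("pacea.data").joinpath("base_case.yaml").read_text()
    return load_parameters(text)


# --------------------------------------------------------------------------
# serialization

def _num(x: float):
    """Shortest-repr number for canonical YAML output."""
    if float(x) == int(x) and abs(x) < 1e15:
        return int(x)
    return float(x)


def _param_node(p: Param):
    if p.lower is None and p.upper is None and p.dist is None:
        return _num(p.value)
    node = {"value": _num(p.value)}
    if p.lower is not None:
        node["lower"] = _num(p.lower)
    if p.upper is not None:
        node["upper"] = _num(p.upper)
    if p.dist is not None:
        node["dist"] = p.dist
    return node


def _band_nodes(table: AgeBandTable):
    out = []
    for b in table.bands:
        node = {"age_lo": b.age_lo, "age_hi": b.age_hi}
        pn = _param_node(b.param)
        if isinstance(pn, dict):
            node.update(pn)
        else:
            node["value"] = pn
        out.append(node)
    return out


def serialize_parameters(mp: ModelParameters) -> str:
    """Canonical YAML rendering of a parameter set (inverse of loading)."""
    pr = mp.programme
    doc = {
        "settings": {
            "annual_discount_rate": _num(mp.settings.annual_discount_rate),
            "cycle_length_months": mp.settings.cycle_length_months,
            "starting_age": _param_node(mp.settings.starting_age),
            "max_age": mp.settings.max_age,
            "wtp_threshold": _num(mp.settings.wtp_threshold),
        },
        "programme": {
            "n_recruited": pr.n_recruited,
            "n_completers": pr.n_completers,
            "dropout_counts": dict(zip(DROPOUT_STAGES, pr.dropout_counts)),
            "completion": {"lower": _num(pr.completion.lower),
                           "upper": _num(pr.completion.upper),
                           "dist": pr.completion.dist},
            "general_cost_per_recruit": _param_node(pr.general_cost_per_recruit),
            "sports_cost_per_completer": _param_node(pr.sports_cost_per_completer),
            "sports_cost_per_noncompleter": _param_node(pr.sports_cost_per_noncompleter),
            "stage_cost_components": {
                "induction": _num(pr.stage_cost_components.induction),
                "membership_per_month": _num(pr.stage_cost_components.membership_per_month),
                "membership_months": list(pr.stage_cost_components.membership_months),
                "follow_up": _num(pr.stage_cost_components.follow_up),
                "communication": _num(pr.stage_cost_components.communication),
            },
            "duration_of_effect_months": _param_node(pr.duration_of_effect_months),
            "baseline_activity": {lv: _param_node(getattr(pr.baseline_activity, lv))
                                  for lv in LEVELS},
            "followup_activity": {lv: _param_node(getattr(pr.followup_activity, lv))
                                  for lv in LEVELS},
        },
        "relative_risks": {
            d: {"moderate": _param_node(mp.relative_risks.for_disease(d).moderate),
                "high": _param_node(mp.relative_risks.for_disease(d).high)}
            for d in DISEASES
        },
        "mortality_rrs": {
            d: {"cvd": _param_node(mp.mortality_rrs.for_disease(d).cvd),
                "non_cvd": _param_node(mp.mortality_rrs.for_disease(d).non_cvd)}
            for d in DISEASES
        },
        "utilities": {
            "age_bands": _band_nodes(mp.utilities.age_bands),
            "chd_first_event": _param_node(mp.utilities.chd_first_event),
            "chd_post_event": _param_node(mp.utilities.chd_post_event),
            "stroke_first_event": _param_node(mp.utilities.stroke_first_event),
            "stroke_post_event": _param_node(mp.utilities.stroke_post_event),
            "diabetes": _param_node(mp.utilities.diabetes),
            "mh_gain_moderate": _param_node(mp.utilities.mh_gain_moderate),
            "mh_gain_high": _param_node(mp.utilities.mh_gain_high),
            "per_halfhour_gain": _num(mp.utilities.per_halfhour_gain),
            "extra_hours_moderate": _num(mp.utilities.extra_hours_moderate),
            "extra_hours_high": _num(mp.utilities.extra_hours_high),
        },
        "diseases": {},
    }
    for d in DISEASES:
        dp = mp.disease(d)
        node = {"incidence": _band_nodes(dp.incidence)}
        if dp.fatal_fraction is not None:
            node["fatal_fraction"] = _band_nodes(dp.fatal_fraction)
        if dp.first_event_cost is not None:
            node["first_event_cost"] = _param_node(dp.first_event_cost)
        node["annual_state_cost"] = _param_node(dp.annual_state_cost)
        doc["diseases"][d] = node
    return yaml.safe_dump(doc, sort_keys=False)


# --------------------------------------------------------------------------
# operations

def mental_health_gain(extra_hours_per_week: float, per_halfhour_gain: float) -> float:
    """Annual mental-wellbeing QALY gain from extra weekly activity.

    Each additional half-hour of activity per week, sustained over a
    52-week year, contributes ``per_halfhour_gain`` QALYs.
    """
    if extra_hours_per_week < 0:
        raise ValueError("extra hours per week must be >= 0")
    return extra_hours_per_week * 2 * 52 * per_halfhour_gain


# --------------------------------------------------------------------------
# scalar-parameter registry (used by one-way and probabilistic SA)

def iter_scalar_params(mp: ModelParameters) -> Iterator[tuple[str, Param]]:
    """Yield ``(dotted_path, Param)`` for every scalar with a sensitivity range."""
    yield "settings.starting_age", mp.settings.starting_age
    pr = mp.programme
    yield "programme.completion", pr.completion
    yield "programme.general_cost_per_recruit", pr.general_cost_per_recruit
    yield "programme.sports_cost_per_completer", pr.sports_cost_per_completer
    yield "programme.sports_cost_per_noncompleter", pr.sports_cost_per_noncompleter
    yield "programme.duration_of_effect_months", pr.duration_of_effect_months
    for dist_name in ("baseline_activity", "followup_activity"):
        dist = getattr(pr, dist_name)
        for lv in ("moderate", "high"):
            yield f"programme.{dist_name}.{lv}", getattr(dist, lv)
    for d in DISEASES:
        rr = mp.relative_risks.for_disease(d)
        yield f"relative_risks.{d}.moderate", rr.moderate
        yield f"relative_risks.{d}.high", rr.high
    for d in DISEASES:
        mr = mp.mortality_rrs.for_disease(d)
        yield f"mortality_rrs.{d}.cvd", mr.cvd
        yield f"mortality_rrs.{d}.non_cvd", mr.non_cvd
    for i, band in enumerate(mp.utilities.age_bands.bands):
        yield f"utilities.age_bands.{i}", band.param
    for name in ("chd_first_event", "chd_post_event", "stroke_first_event",
                 "stroke_post_event", "diabetes", "mh_gain_moderate", "mh_gain_high"):
        yield f"utilities.{name}", getattr(mp.utilities, name)
    for d in DISEASES:
        dp = mp.disease(d)
        for i, band in enumerate(dp.incidence.bands):
            yield f"diseases.{d}.incidence.{i}", band.param
        if dp.fatal_fraction is not None:
            for i, band in enumerate(dp.fatal_fraction.bands):
                yield f"diseases.{d}.fatal_fraction.{i}", band.param
        if dp.first_event_cost is not None:
            yield f"diseases.{d}.first_event_cost", dp.first_event_cost
        yield f"diseases.{d}.annual_state_cost", dp.annual_state_cost


def get_param(mp: ModelParameters, path: str) -> Param:
    for p, param in iter_scalar_params(mp):
        if p == path:
            return param
    raise ParameterError(f"unknown parameter id {path!r}")


def _with_value(param: Param, value: float) -> Param:
    """Param with a new value; bounds widen if the value falls outside them
    (probabilistic draws extend beyond the printed 95 % interval by design)."""
    lower = None if param.lower is None else min(param.lower, value)
    upper = None if param.upper is None else max(param.upper, value)
    return dataclasses.replace(param, value=value, lower=lower, upper=upper)


def _replace_band(table: AgeBandTable, index: int, value: float) -> AgeBandTable:
    bands = list(table.bands)
    bands[index] = dataclasses.replace(
        bands[index], param=_with_value(bands[index].param, value))
    return AgeBandTable(tuple(bands))


def set_value(mp: ModelParameters, path: str, value: float) -> ModelParameters:
    """Return a copy of ``mp`` with the scalar at ``path`` set to ``value``.

    Activity-distribution fractions are renormalized (the other two levels
    scaled proportionally) so the composition stays on the simplex.
    """
    get_param(mp, path)  # raises on unknown path
    parts = path.split(".")
    rep = dataclasses.replace
    if parts[0] == "settings":
        return rep(mp, settings=rep(mp.settings,
                                    starting_age=_with_value(mp.settings.starting_age, value)))
    if parts[0] == "programme":
        pr = mp.programme
        if parts[1] in ("baseline_activity", "followup_activity"):
            dist = getattr(pr, parts[1]).with_fraction(parts[2], value)
            return rep(mp, programme=rep(pr, **{parts[1]: dist}))
        field = parts[1]
        return rep(mp, programme=rep(pr, **{field: _with_value(getattr(pr, field), value)}))
    if parts[0] == "relative_risks":
        rrset = mp.relative_risks
        d = getattr(rrset, parts[1])
        d2 = rep(d, **{parts[2]: _with_value(getattr(d, parts[2]), value)})
        return rep(mp, relative_risks=rep(rrset, **{parts[1]: d2}))
    if parts[0] == "mortality_rrs":
        mrset = mp.mortality_rrs
        d = getattr(mrset, parts[1])
        d2 = rep(d, **{parts[2]: _with_value(getattr(d, parts[2]), value)})
        return rep(mp, mortality_rrs=rep(mrset, **{parts[1]: d2}))
    if parts[0] == "utilities":
        ut = mp.utilities
        if parts[1] == "age_bands":
            return rep(mp, utilities=rep(ut, age_bands=_replace_band(
                ut.age_bands, int(parts[2]), value)))
        return rep(mp, utilities=rep(ut, **{parts[1]: _with_value(getattr(ut, parts[1]),
                                                                  value)}))
    if parts[0] == "diseases":
        dp = mp.disease(parts[1])
        if parts[2] in ("incidence", "fatal_fraction"):
            table = getattr(dp, parts[2])
            dp2 = rep(dp, **{parts[2]: _replace_band(table, int(parts[3]), value)})
        else:
            dp2 = rep(dp, **{parts[2]: _with_value(getattr(dp, parts[2]), value)})
        return rep(mp, **{parts[1]: dp2})
    raise ParameterError(f"unknown parameter id {path!r}")
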