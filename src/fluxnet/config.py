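"""Ecosystem model registry: components, parameters, constraints, de-lumping.

A :class:`ModelSpec` holds the complete structural description of the
ecosystem — which phytoplankton, bacteria, DOM/POM, nutrient, micronutrient
and inhibitor components exist, every parameter with its bounds and
optimize flag, curation constraints, and the observation mappings that tie
model components to observed time series.  The de-lump operation grows the
registry by splitting components into daughter pairs that inherit the
parent's parameters, mimicking speciation.

The on-disk format is a sectioned YAML document (schema documented in the
README); :func:`load_model_config` / :func:`save_model_config` round-trip
it losslessly.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Param",
    "ComponentSpec",
    "ObservationMapping",
    "ConstraintRecord",
    "ConstraintSet",
    "ModelSpec",
    "ConfigError",
    "load_model_config",
    "save_model_config",
    "validate_spec",
    "apply_constraints",
    "delump",
    "SPLITTABLE",
]

#: compartments whose components are split by the default de-lump policy
SPLITTABLE = ("phytoplankton", "bacteria", "DOM", "POM")

COMPARTMENTS = (
    "phytoplankton",
    "bacteria",
    "DOM",
    "POM",
    "nutrient",
    "micronutrient",
    "inhibitor",
)

# keyed tables whose entries are *distributed* over a split target component
# (fractions of a flux: halved across daughters so sums are preserved);
# everything else keyed by component id is *intensive* (copied unchanged,
# e.g. half-saturation constants, so shared Monod denominators are preserved).
_DISTRIBUTIVE_TABLES = {"Fe", "Fx", "Pom"}

# per-component parameters that scale with pool size: halved on split so the
# daughter pair behaves exactly like the parent (e.g. the dormancy floor)
_EXTENSIVE_PARAMS = {"Cflr"}


class ConfigError(ValueError):
    """Raised when a model configuration fails validation."""


@dataclass
class Param:
    """A scalar model parameter with bounds and an optimize flag."""

    value: float
    lo: float = 0.0
    hi: float = math.inf
    optimize: bool = False

    def copy(self) -> "Param":
        return Param(self.value, self.lo, self.hi, self.optimize)

    def as_dict(self) -> dict:
        d: dict = {"value": float(self.value)}
        if self.lo != 0.0:
            d["lo"] = float(self.lo)
        if not math.isinf(self.hi):
            d["hi"] = float(self.hi)
        if self.optimize:
            d["optimize"] = True
        return d

    @staticmethod
    def from_any(x) -> "Param":
        if isinstance(x, Param):
            return x.copy()
        if isinstance(x, dict):
            return Param(
                float(x["value"]),
                float(x.get("lo", 0.0)),
                float(x.get("hi", math.inf)),
                bool(x.get("optimize", False)),
            )
        return Param(float(x))


@dataclass
class ComponentSpec:
    """One model component (a species, OM pool, nutrient, ...)."""

    id: str
    compartment: str
    c0: Param = field(default_factory=lambda: Param(0.0))
    is_cryptic: bool = False
    parent_id: str | None = None
    pom_partner: str | None = None
    #: conversion: model µmolC/L = observed units × carbon_per_unit
    carbon_per_unit: float = 1.0
    #: DOM class for diet analyses: "storage", "cell_wall" or "other"
    dom_class: str = "other"
    label: str = ""
    params: dict[str, Param] = field(default_factory=dict)
    tables: dict[str, dict[str, Param]] = field(default_factory=dict)

    def copy(self) -> "ComponentSpec":
        c = ComponentSpec(
            self.id, self.compartment, self.c0.copy(), self.is_cryptic,
            self.parent_id, self.pom_partner, self.carbon_per_unit,
            self.dom_class, self.label,
        )
        c.params = {k: p.copy() for k, p in self.params.items()}
        c.tables = {n: {k: p.copy() for k, p in t.items()} for n, t in self.tables.items()}
        return c

    def p(self, name: str, default: float = 0.0) -> float:
        prm = self.params.get(name)
        return prm.value if prm is not None else default


@dataclass
class ObservationMapping:
    """Maps an observed series onto a weighted sum of model components.

    Targets are (component id | "@compartment", coefficient) pairs; the
    modeled series is sum(coef * C_i) in the observation's own units.
    """

    series_id: str
    targets: list[tuple[str, float]]
    weight: float = 1.0


@dataclass
class ConstraintRecord:
    """One curation record from the literature-constraint table.

    kind: "fix" (pin value, stop optimizing), "range" (narrow bounds) or
    "forbid_uptake" (remove a bacterium-DOM affinity; parameter = DOM id).
    """

    scope: str              # "comp", "comp/param" or "comp/table/key"
    parameter: str
    kind: str
    value_lo: float | None = None
    value_hi: float | None = None
    note: str = ""


@dataclass
class ConstraintSet:
    records: list[ConstraintRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


@dataclass
class ModelSpec:
    """The full ecosystem registry."""

    components: dict[str, ComponentSpec] = field(default_factory=dict)
    environment: dict[str, Param] = field(default_factory=dict)
    #: per-compartment stoichiometry, e.g. {"bacteria": {"n_to_c": .., "p_to_c": ..}}
    stoichiometry: dict[str, dict[str, float]] = field(default_factory=dict)
    mappings: list[ObservationMapping] = field(default_factory=list)
    name: str = "model"

    # ---- convenience selectors -------------------------------------------
    def ids(self, compartment: str | None = None) -> list[str]:
        if compartment is None:
            return list(self.components)
        return [c.id for c in self.components.values() if c.compartment == compartment]

    def comp(self, cid: str) -> ComponentSpec:
        return self.components[cid]

    def env(self, name: str, default: float = 0.0) -> float:
        prm = self.environment.get(name)
        return prm.value if prm is not None else default

    def copy(self) -> "ModelSpec":
        s = ModelSpec(name=self.name)
        s.components = {k: c.copy() for k, c in self.components.items()}
        s.environment = {k: p.copy() for k, p in self.environment.items()}
        s.stoichiometry = copy.deepcopy(self.stoichiometry)
        s.mappings = [
            ObservationMapping(m.series_id, list(m.targets), m.weight) for m in self.mappings
        ]
        return s

    # ---- lineage ----------------------------------------------------------
    def resolve_id(self, cid: str) -> str | None:
        """Resolve ``cid`` to itself or its nearest existing ancestor.

        Component ids are hierarchical ("phy.a.b" is a daughter of "phy.a"),
        so a species named at a finer de-lump level than the current spec
        maps onto the lumped pool that currently represents it.
        """
        cur = cid
        while cur:
            if cur in self.components:
                return cur
            if "." not in cur:
                return None
            cur = cur.rsplit(".", 1)[0]
        return None

    def leaves_under(self, cid: str) -> list[str]:
        """All current components descending from (or equal to) ``cid``."""
        pref = cid + "."
        return [k for k in self.components if k == cid or k.startswith(pref)]


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_spec(spec: ModelSpec) -> list[str]:
    """Return a list of human-readable violations (empty if valid)."""
    issues: list[str] = []
    seen: set[str] = set()
    for cid, c in spec.components.items():
        if cid != c.id:
            issues.append(f"component key {cid!r} != id {c.id!r}")
        if c.id in seen:
            issues.append(f"duplicate component id {c.id!r}")
        seen.add(c.id)
        if c.compartment not in COMPARTMENTS:
            issues.append(f"{c.id}: unknown compartment {c.compartment!r}")
        if (c.pom_partner is not None) != (c.compartment == "POM"):
            issues.append(f"{c.id}: pom_partner must be set iff compartment is POM")
        if c.pom_partner is not None:
            tgt = spec.components.get(c.pom_partner)
            if tgt is None or tgt.compartment != "DOM":
                issues.append(f"{c.id}: pom_partner {c.pom_partner!r} is not an existing DOM")
        if c.parent_id is not None:
            par = spec.components.get(c.parent_id)
            if par is not None and par.compartment != c.compartment:
                issues.append(f"{c.id}: parent {c.parent_id!r} in different compartment")
        for name, prm in list(c.params.items()) + [("c0", c.c0)]:
            if prm.lo > prm.hi:
                issues.append(f"{c.id}.{name}: bound inversion lo={prm.lo} > hi={prm.hi}")
            if not (prm.lo - 1e-12 <= prm.value <= prm.hi + 1e-12):
                issues.append(f"{c.id}.{name}: value {prm.value} outside [{prm.lo}, {prm.hi}]")
        for tname, table in c.tables.items():
            for key, prm in table.items():
                if key not in spec.components and not key.startswith("@"):
                    issues.append(f"{c.id}.{tname}[{key}]: unknown component")
                if prm.lo > prm.hi:
                    issues.append(f"{c.id}.{tname}[{key}]: bound inversion")
        for tname in ("Fe", "Fx"):
            table = c.tables.get(tname)
            if table:
                tot = sum(p.value for p in table.values())
                if tot > 1.0 + 1e-9:
                    issues.append(f"{c.id}: {tname} fractions sum to {tot:.4g} > 1")
        ksh = c.tables.get("Ksh")
        if ksh:
            for key, prm in ksh.items():
                if prm.value <= 0:
                    issues.append(f"{c.id}.Ksh[{key}]: must be > 0 (omit the pair to forbid uptake)")
        yh = c.params.get("Yh")
        if yh is not None and not (0 < yh.value <= 1):
            issues.append(f"{c.id}: yield Yh={yh.value} outside (0, 1]")
    for m in spec.mappings:
        for tid, coef in m.targets:
            if coef <= 0:
                issues.append(f"mapping {m.series_id}: coefficient {coef} not > 0")
            if tid.startswith("@"):
                if tid[1:] not in COMPARTMENTS:
                    issues.append(f"mapping {m.series_id}: unknown compartment {tid!r}")
            elif spec.resolve_id(tid) is None:
                issues.append(f"mapping {m.series_id}: unresolvable target {tid!r}")
    return issues


# --------------------------------------------------------------------------
# YAML round-trip
# --------------------------------------------------------------------------

def _comp_to_dict(c: ComponentSpec) -> dict:
    d: dict = {"id": c.id, "compartment": c.compartment, "c0": c.c0.as_dict()}
    if c.is_cryptic:
        d["is_cryptic"] = True
    if c.parent_id:
        d["parent_id"] = c.parent_id
    if c.pom_partner:
        d["pom_partner"] = c.pom_partner
    if c.carbon_per_unit != 1.0:
        d["carbon_per_unit"] = c.carbon_per_unit
    if c.dom_class != "other":
        d["dom_class"] = c.dom_class
    if c.label:
        d["label"] = c.label
    if c.params:
        d["params"] = {k: p.as_dict() for k, p in c.params.items()}
    if c.tables:
        d["tables"] = {n: {k: p.as_dict() for k, p in t.items()} for n, t in c.tables.items()}
    return d


def _comp_from_dict(d: dict) -> ComponentSpec:
    c = ComponentSpec(
        id=str(d["id"]),
        compartment=str(d["compartment"]),
        c0=Param.from_any(d.get("c0", 0.0)),
        is_cryptic=bool(d.get("is_cryptic", False)),
        parent_id=d.get("parent_id"),
        pom_partner=d.get("pom_partner"),
        carbon_per_unit=float(d.get("carbon_per_unit", 1.0)),
        dom_class=str(d.get("dom_class", "other")),
        label=str(d.get("label", "")),
    )
    for k, v in (d.get("params") or {}).items():
        c.params[k] = Param.from_any(v)
    for n, t in (d.get("tables") or {}).items():
        c.tables[n] = {k: Param.from_any(v) for k, v in t.items()}
    return c


def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "name": spec.name,
        "environment": {k: p.as_dict() for k, p in spec.environment.items()},
        "stoichiometry": spec.stoichiometry,
        "components": [_comp_to_dict(c) for c in spec.components.values()],
        "mappings": [
            {"series_id": m.series_id, "weight": m.weight,
             "targets": [[t, c] for t, c in m.targets]}
            for m in spec.mappings
        ],
    }


def spec_from_dict(d: dict) -> ModelSpec:
    spec = ModelSpec(name=str(d.get("name", "model")))
    for k, v in (d.get("environment") or {}).items():
        spec.environment[k] = Param.from_any(v)
    spec.stoichiometry = {k: dict(v) for k, v in (d.get("stoichiometry") or {}).items()}
    for cd in d.get("components") or []:
        c = _comp_from_dict(cd)
        if c.id in spec.components:
            raise ConfigError(f"duplicate component id {c.id!r}")
        spec.components[c.id] = c
    for md in d.get("mappings") or []:
        spec.mappings.append(ObservationMapping(
            series_id=str(md["series_id"]),
            targets=[(str(t), float(c)) for t, c in md["targets"]],
            weight=float(md.get("weight", 1.0)),
        ))
    return spec


def save_model_config(spec: ModelSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False, default_flow_style=None)


def load_model_config(path) -> ModelSpec:
    """Load and validate a model configuration file."""
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    spec = spec_from_dict(d)
    issues = validate_spec(spec)
    if issues:
        raise ConfigError("invalid model config:\n  " + "\n  ".join(issues))
    return spec


# --------------------------------------------------------------------------
# curation constraints
# --------------------------------------------------------------------------

def _parse_scope(scope: str) -> list[str]:
    # "/" separates scope parts; component ids themselves contain "."
    return scope.split("/")


def apply_constraints(spec: ModelSpec, constraints: ConstraintSet) -> ModelSpec:
    """Apply curation records to a spec (idempotent; returns the same spec)."""
    for rec in constraints:
        parts = _parse_scope(rec.scope)
        cid = parts[0]
        c = spec.components.get(cid)
        if c is None:
            raise ConfigError(f"constraint scope {rec.scope!r}: unknown component {cid!r}")
        if rec.kind == "forbid_uptake":
            # scope "bact", parameter = DOM id (or "bact.Ksh" with parameter=dom)
            dom = rec.parameter
            table = c.tables.get("Ksh", {})
            # no-uptake sentinel: the pair is simply absent from the table,
            # so flux code never sees (let alone divides by) a sentinel value
            table.pop(dom, None)
            c.tables["Ksh"] = table
            continue
        if len(parts) == 3:
            tname, key = parts[1], parts[2]
            table = c.tables.get(tname)
            if table is None or key not in table:
                raise ConfigError(f"constraint scope {rec.scope!r}: no table entry")
            prm = table[key]
        else:
            pname = parts[1] if len(parts) == 2 else rec.parameter
            if pname == "c0":
                prm = c.c0
            else:
                prm2 = c.params.get(pname)
                if prm2 is None:
                    raise ConfigError(f"constraint scope {rec.scope!r}: unknown parameter {pname!r}")
                prm = prm2
        if rec.kind == "fix":
            prm.value = float(rec.value_lo)
            prm.lo = min(prm.lo, prm.value)
            prm.hi = max(prm.hi, prm.value)
            prm.optimize = False
        elif rec.kind == "range":
            if rec.value_lo is not None:
                prm.lo = float(rec.value_lo)
            if rec.value_hi is not None:
                prm.hi = float(rec.value_hi)
            prm.value = min(max(prm.value, prm.lo), prm.hi)
        else:
            raise ConfigError(f"unknown constraint kind {rec.kind!r}")
    return spec


def load_constraints(path) -> ConstraintSet:
    """Read a curation table (TSV: scope, parameter, kind, value_lo, value_hi, note)."""
    import csv

    cs = ConstraintSet()
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            cs.records.append(ConstraintRecord(
                scope=row["scope"],
                parameter=row.get("parameter", ""),
                kind=row["kind"],
                value_lo=float(row["value_lo"]) if row.get("value_lo") else None,
                value_hi=float(row["value_hi"]) if row.get("value_hi") else None,
                note=row.get("note", ""),
            ))
    return cs


def save_constraints(cs: ConstraintSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("scope\tparameter\tkind\tvalue_lo\tvalue_hi\tnote\n")
        for r in cs:
            lo = "" if r.value_lo is None else repr(r.value_lo)
            hi = "" if r.value_hi is None else repr(r.value_hi)
            fh.write(f"{r.scope}\t{r.parameter}\t{r.kind}\t{lo}\t{hi}\t{r.note}\n")


# --------------------------------------------------------------------------
# de-lumping
# --------------------------------------------------------------------------

def delump(
    spec: ModelSpec,
    overrides: ConstraintSet | None = None,
    split: list[str] | None = None,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ModelSpec:
    """Split components into daughter pairs that inherit the parent's genome.

    ``split`` lists component ids to split; by default every component in a
    splittable compartment (phytoplankton, bacteria, DOM, POM) is split.
    Daughters are named ``<parent>.a`` / ``<parent>.b``, inherit every
    parameter value, record ``parent_id``, and start at half the parent's
    initial concentration.  Producer-side distribution fractions that target
    a split substrate are halved across its daughters; half-saturation
    constants are copied, so the split is exactly flux-neutral until
    optimization diversifies the daughters.  ``overrides`` (applied after
    inheritance) carry the curation knowledge for the new level, e.g.
    forbidding a daughter from taking up a substrate.  ``jitter`` optionally
    perturbs daughters' optimizable parameters by a fraction of their range
    to break twin symmetry (off by default).
    """
    if split is None:
        split = [c.id for c in spec.components.values() if c.compartment in SPLITTABLE]
    split_set = set(split)
    for cid in split_set:
        if cid not in spec.components:
            raise ConfigError(f"delump: unknown component {cid!r}")

    def children(cid: str) -> list[str]:
        return [cid + ".a", cid + ".b"] if cid in split_set else [cid]

    out = ModelSpec(name=spec.name)
    out.environment = {k: p.copy() for k, p in spec.environment.items()}
    out.stoichiometry = copy.deepcopy(spec.stoichiometry)

    for cid, c in spec.components.items():
        for di, new_id in enumerate(children(cid)):
            d = c.copy()
            d.id = new_id
            if cid in split_set:
                d.parent_id = cid
                d.c0 = Param(c.c0.value / 2.0, c.c0.lo / 2.0,
                             c.c0.hi / 2.0 if not math.isinf(c.c0.hi) else math.inf,
                             c.c0.optimize)
                for pname in _EXTENSIVE_PARAMS:
                    prm = d.params.get(pname)
                    if prm is not None:
                        prm.value /= 2.0
                        prm.lo /= 2.0
                        if not math.isinf(prm.hi):
                            prm.hi /= 2.0
            if c.pom_partner is not None and c.pom_partner in split_set:
                # paired daughter if both split; else the first partner daughter
                d.pom_partner = children(c.pom_partner)[di if cid in split_set else 0]
            # remap keyed tables onto the new registry
            for tname, table in list(d.tables.items()):
                new_table: dict[str, Param] = {}
                for key, prm in table.items():
                    kids = children(key) if key in split_set else [key]
                    for kid in kids:
                        np_ = prm.copy()
                        if len(kids) == 2 and tname in _DISTRIBUTIVE_TABLES:
                            np_.value /= 2.0
                            np_.lo /= 2.0
                            if not math.isinf(np_.hi):
                                np_.hi /= 2.0
                        new_table[kid] = np_
                d.tables[tname] = new_table
            out.components[new_id] = d

    for m in spec.mappings:
        new_targets: list[tuple[str, float]] = []
        for tid, coef in m.targets:
            if tid in split_set:
                for kid in children(tid):
                    new_targets.append((kid, coef))
            else:
                new_targets.append((tid, coef))
        out.mappings.append(ObservationMapping(m.series_id, new_targets, m.weight))

    if overrides is not None:
        apply_constraints(out, overrides)

    if jitter > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        for c in out.components.values():
            if c.parent_id is None:
                continue
            for prm in list(c.params.values()) + [p for t in c.tables.values() for p in t.values()]:
                if prm.optimize and math.isfinite(prm.hi):
                    span = prm.hi - prm.lo
                    prm.value = float(np.clip(
                        prm.value + rng.uniform(-jitter, jitter) * span, prm.lo, prm.hi))
    return out
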