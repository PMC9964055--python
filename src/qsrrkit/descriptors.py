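"""pH-dependent molecular descriptors by microspecies-fraction weighting.

A molecule with ionizable sites exists at any pH as a mixture of protonation
states (microspecies), each with its own descriptor values. A pH-aware
descriptor matrix is built by averaging each descriptor over the species,
weighted by the species' equilibrium population at that pH, and appending the
distribution coefficient logD for the same pH as an extra descriptor.

Species populations are modeled with the sequential-macrostate
(Henderson–Hasselbalch ladder) approximation: with pKa values sorted
ascending, the state that has lost ``j`` protons has relative population
``10 ** sum(pH - pKa_i, i <= j)``. Users with externally computed
full-microstate distributions can bypass :func:`speciate` and pass their own
fractions to :func:`weighted_descriptors`.

logD is consumed as an input (typically from vendor software), never
computed here.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "SpeciationResult",
    "MicrospeciesProfile",
    "speciate",
    "weighted_descriptors",
    "build_matrix",
    "profiles_from_json",
]


@dataclass(frozen=True)
class SpeciationResult:
    """Population fractions of each species at one pH; fractions sum to 1."""

    fractions: dict[str, float]
    ph: float

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"fractions sum to {total}, expected 1")
        if any(f < -1e-15 or f > 1 + 1e-15 for f in self.fractions.values()):
            raise ValidationError("fractions must lie in [0, 1]")


@dataclass
class MicrospeciesProfile:
    """Per-compound species descriptor vectors plus ionization metadata.

    ``species`` maps species label -> {descriptor name: value}; all species
    must share the same descriptor-name set. ``logd_by_ph`` maps pH to the
    externally supplied logD.
    """

    compound_id: str
    species: dict[str, dict[str, float]]
    pka_values: list[float] = field(default_factory=list)
    site_types: list[str] = field(default_factory=list)
    logd_by_ph: dict[float, float] = field(default_factory=dict)

    def descriptor_names(self) -> list[str]:
        names = None
        for label, vec in self.species.items():
            cur = set(vec)
            if names is None:
                names = cur
            elif cur != names:
                missing = sorted(names.symmetric_difference(cur))
                raise ValidationError(
                    f"compound {self.compound_id!r}: species {label!r} "
                    f"descriptor-name mismatch, differing names: {missing}"
                )
        return sorted(names or [])

    def logd_at(self, ph: float) -> float:
        if not self.logd_by_ph:
            raise ValidationError(
                f"compound {self.compound_id!r} has no logD values"
            )
        for key, val in self.logd_by_ph.items():
            if abs(key - ph) < 1e-9:
                return float(val)
        phs = np.array(sorted(self.logd_by_ph))
        vals = np.array([self.logd_by_ph[k] for k in phs])
        return float(np.interp(ph, phs, vals))


def _charge_label(charge: int) -> str:
    if charge == 0:
        return "neutral"
    if charge > 0:
        return "cation" if charge == 1 else f"cation{charge}"
    return "anion" if charge == -1 else f"anion{-charge}"


def species_labels(pka_values: Sequence[float], site_types: Sequence[str]) -> list[str]:
    """Labels of the sequential macrostates, most-protonated first.

    State ``j`` has lost ``j`` protons; its net charge is the number of basic
    sites minus ``j`` (all basic sites protonated in state 0).
    """
    n_basic = sum(1 for s in site_types if s == "basic")
    return [_charge_label(n_basic - j) for j in range(len(pka_values) + 1)]


def speciate(
    pka_values: Sequence[float], site_types: Sequence[str], ph: float
) -> SpeciationResult:
    """Equilibrium fractions of the protonation macrostates at ``ph``.

    ``pka_values`` must be sorted ascending (ladder order); ``site_types``
    entries are ``"acidic"`` or ``"basic"`` and only affect species labels.
    An empty pKa list yields a single neutral species with fraction 1.
    """
    if not math.isfinite(ph):
        raise ValidationError("ph must be finite")
    pka_values = list(pka_values)
    site_types = list(site_types)
    if len(pka_values) != len(site_types):
        raise ValidationError("pka_values and site_types must have equal length")
    if any(not math.isfinite(p) for p in pka_values):
        raise ValidationError("pKa values must be finite")
    if any(b < a for a, b in zip(pka_values, pka_values[1:])):
        raise ValidationError("pka_values must be sorted ascending")
    bad = sorted(set(site_types) - {"acidic", "basic"})
    if bad:
        raise ValidationError(f"unknown site types: {bad}")

    labels = species_labels(pka_values, site_types)
    # log10 relative population of state j (j protons removed)
    logw = np.concatenate([[0.0], np.cumsum(ph - np.asarray(pka_values, float))])
    w = np.power(10.0, logw - logw.max())
    fractions = w / w.sum()
    return SpeciationResult(
        fractions={lab: float(f) for lab, f in zip(labels, fractions)}, ph=float(ph)
    )


def weighted_descriptors(
    profile: MicrospeciesProfile,
    speciation: SpeciationResult,
    include_logd: bool = True,
) -> dict[str, float]:
    """Fraction-weighted average of each descriptor over the microspecies.

    Every output descriptor is ``sum_s fraction_s * value_s``; the compound's
    logD at the speciation pH is appended under the name ``"logD"`` when
    ``include_logd`` is set.
    """
    names = profile.descriptor_names()
    missing = sorted(set(speciation.fractions) - set(profile.species))
    if missing:
        raise ValidationError(
            f"compound {profile.compound_id!r}: no descriptor vector for "
            f"species {missing}"
        )
    out = {name: 0.0 for name in names}
    for label, frac in speciation.fractions.items():
        vec = profile.species[label]
        for name in names:
            out[name] += frac * float(vec[name])
    if include_logd:
        if "logD" in out:
            raise ValidationError("'logD' clashes with an existing descriptor name")
        out["logD"] = profile.logd_at(speciation.ph)
    return out


def build_matrix(
    profiles: Sequence[MicrospeciesProfile],
    ph: float,
    include_logd: bool = True,
) -> pd.DataFrame:
    """Assemble the compounds × descriptors matrix for one pH.

    Rows keep the input profile order; columns are the (shared) descriptor
    names in sorted order with ``logD`` appended last.
    """
    if not profiles:
        raise ValidationError("no profiles given")
    seen = set()
    for prof in profiles:
        if prof.compound_id in seen:
            raise ValidationError(f"duplicate compound_id {prof.compound_id!r}")
        seen.add(prof.compound_id)
    ref_names = profiles[0].descriptor_names()
    rows = []
    for prof in profiles:
        if prof.descriptor_names() != ref_names:
            raise ValidationError(
                f"compound {prof.compound_id!r} descriptor names differ from "
                f"first profile"
            )
        spec_result = speciate(prof.pka_values, prof.site_types, ph)
        rows.append(weighted_descriptors(prof, spec_result, include_logd))
    columns = ref_names + (["logD"] if include_logd else [])
    return pd.DataFrame(
        rows, index=pd.Index([p.compound_id for p in profiles], name="id")
    )[columns]


def profiles_from_json(path: str | Path) -> list[MicrospeciesProfile]:
    """Load microspecies profiles from a JSON file.

    Expected layout: a list of objects with keys ``compound_id``, ``species``
    (label -> {descriptor: value}), optional ``pka_values``, ``site_types``
    and ``logd_by_ph`` (pH-string -> value).
    """
    raw = json.loads(Path(path).read_text())
    profiles = []
    for entry in raw:
        profiles.append(
            MicrospeciesProfile(
                compound_id=entry["compound_id"],
                species=entry["species"],
                pka_values=list(entry.get("pka_values", [])),
                site_types=list(entry.get("site_types", [])),
                logd_by_ph={
                    float(k): float(v)
                    for k, v in entry.get("logd_by_ph", {}).items()
                },
            )
        )
    return profiles
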