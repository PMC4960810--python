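"""Run configuration: typed, validated, hashable study settings.

A :class:`RunConfig` bundles everything a full pipeline run needs (study
design, PK/PD/link parameters, noise levels, dose regimens, seed).  The
packaged versioned default configuration encodes the study conditions the
synthetic generator emulates; load it with :func:`load_default_config`.

The configuration hash (:meth:`RunConfig.config_hash`) is embedded in every
numeric output artifact together with the seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .pdlink import TumorPDParams
from .pksim import DoseRegimen, TwoCompartmentParams
from .synthetic import LinkParams, NoiseSpec, StudyDesign

__all__ = ["RunConfig", "load_default_config", "DEFAULT_CONFIG_RESOURCE"]

DEFAULT_CONFIG_RESOURCE = "default_config.json"


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration for a simulate -> analyse -> fit pipeline run."""

    seed: int
    study: StudyDesign
    pk: TwoCompartmentParams
    pd: TumorPDParams
    link: LinkParams
    noise: NoiseSpec
    regimens: tuple[DoseRegimen, ...]
    growth_days: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)
    n_growth_subjects: int = 5
    horizon_day: float = 21.0
    molar_mass_g_mol: float | None = None
    imaging_background_counts_per_s: float = 5000.0
    standard_slope_counts_per_uM: float = 1.0e5
    standard_intercept_counts: float = 0.0
    config_version: str = "1.0"
    output_dir: Path | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n_growth_subjects < 1:
            raise ValueError("n_growth_subjects must be >= 1")
        if self.horizon_day <= 0:
            raise ValueError("horizon_day must be positive")
        object.__setattr__(self, "regimens", tuple(self.regimens))
        object.__setattr__(self, "growth_days", tuple(float(d) for d in self.growth_days))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            return cls(
                seed=int(d["seed"]),
                study=StudyDesign(**d["study"]),
                pk=TwoCompartmentParams(**d["pk"]),
                pd=TumorPDParams(**d["pd"]),
                link=LinkParams(**d["link"]),
                noise=NoiseSpec(**d["noise"]),
                regimens=tuple(
                    DoseRegimen(
                        events=tuple((t, x) for t, x in r["events"]),
                        label=r.get("label", ""),
                    )
                    for r in d["regimens"]
                ),
                growth_days=tuple(d.get("growth_days", (0, 3, 6, 9, 12, 15, 18, 21))),
                n_growth_subjects=int(d.get("n_growth_subjects", 5)),
                horizon_day=float(d.get("horizon_day", 21.0)),
                molar_mass_g_mol=d.get("molar_mass_g_mol"),
                imaging_background_counts_per_s=float(
                    d.get("imaging_background_counts_per_s", 5000.0)
                ),
                standard_slope_counts_per_uM=float(
                    d.get("standard_slope_counts_per_uM", 1.0e5)
                ),
                standard_intercept_counts=float(d.get("standard_intercept_counts", 0.0)),
                config_version=str(d.get("config_version", "1.0")),
            )
        except KeyError as exc:
            raise ValueError(f"configuration missing required field {exc.args[0]!r}") from exc

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "config_version": self.config_version,
            "seed": self.seed,
            "study": {
                "dose_mg_per_kg": self.study.dose_mg_per_kg,
                "sampling_times_h": list(self.study.sampling_times_h),
                "n_subjects": self.study.n_subjects,
                "arms": list(self.study.arms),
                "seed": self.study.seed,
            },
            "pk": {"cl": self.pk.cl, "v1": self.pk.v1, "q": self.pk.q, "v2": self.pk.v2},
            "pd": {
                "t0": self.pd.t0,
                "kg": self.pd.kg,
                "imax": self.pd.imax,
                "ic50": self.pd.ic50,
            },
            "link": {"k_in": self.link.k_in, "k_out": self.link.k_out},
            "noise": {
                "conc_cv": self.noise.conc_cv,
                "count_cv": self.noise.count_cv,
                "burden_cv": self.noise.burden_cv,
                "lloq": self.noise.lloq,
            },
            "regimens": [
                {"label": r.label, "events": [list(e) for e in r.events]}
                for r in self.regimens
            ],
            "growth_days": list(self.growth_days),
            "n_growth_subjects": self.n_growth_subjects,
            "horizon_day": self.horizon_day,
            "molar_mass_g_mol": self.molar_mass_g_mol,
            "imaging_background_counts_per_s": self.imaging_background_counts_per_s,
            "standard_slope_counts_per_uM": self.standard_slope_counts_per_uM,
            "standard_intercept_counts": self.standard_intercept_counts,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def config_hash(self) -> str:
        """Short SHA-256 of the canonical JSON form (for provenance)."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def with_seed(self, seed: int) -> "RunConfig":
        from dataclasses import replace

        return replace(
            self, seed=seed, study=StudyDesign(
                dose_mg_per_kg=self.study.dose_mg_per_kg,
                sampling_times_h=self.study.sampling_times_h,
                n_subjects=self.study.n_subjects,
                arms=self.study.arms,
                seed=seed,
            )
        )


def load_default_config() -> RunConfig:
    """Load the packaged versioned default configuration."""
    text = resources.files("prodrugpk.data").joinpath(DEFAULT_CONFIG_RESOURCE).read_text()
    return RunConfig.from_dict(json.loads(text))
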