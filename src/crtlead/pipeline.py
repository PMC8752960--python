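"""End-to-end pipeline: cohort -> coordinates -> leads -> campaign ->
optimization -> statistics -> sensitivity, driven by a single run
configuration (YAML or JSON)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

from . import io as cio
from .anatomy import CohortSpecification, assign_rule_based_fibres, sample_cohort
from .campaign import Subject, campaign_bookkeeping, run_campaign
from .coordinates import compute_uvc, map_aha17
from .eikonal import ConductionParameters
from .leads import VEINS, VEIN_ORDER, locate_vein_line, place_electrodes, place_rv_electrode
from .optimization import cohort_optimal
from .sensitivity import run_oat_sensitivity
from .stats import wilcoxon_signed_rank

log = logging.getLogger("crtlead")

__all__ = ["RunConfiguration", "run_pipeline", "build_subjects", "load_config"]


@dataclass(frozen=True)
class RunConfiguration:
    """Serializable description of a full virtual-trial run."""

    n_hf: int = 2
    n_rr: int = 2
    seed: int = 0
    shape_cv: float = 0.10
    target_edge_length: float = 5.0
    veins: tuple = VEIN_ORDER
    n_electrodes: int = 8
    electrode_spacing_mm: float = 7.5
    basal_z: float = 0.8
    rv_site: str = "APEX"
    cv_fibre: float = 0.5
    k_xf: float = 0.6
    k_fec: float = 5.0
    fec_extent: float = 0.33
    scar_threshold_mm: Optional[float] = None
    run_sensitivity: bool = False
    output_dir: str = "crtlead_output"

    def validate(self) -> None:
        if self.n_hf < 0 or self.n_rr < 0 or self.n_hf + self.n_rr < 1:
            raise ValueError("need at least one subject")
        for v in self.veins:
            if v not in VEINS:
                raise ValueError(f"unknown vein name {v!r}; expected one of {list(VEINS)}")
        if self.rv_site not in ("APEX", "SEPTAL_MID"):
            raise ValueError(f"unknown rv_site {self.rv_site!r}")
        self.conduction().validate()

    def conduction(self) -> ConductionParameters:
        return ConductionParameters(
            cv_fibre=self.cv_fibre,
            k_xf=self.k_xf,
            k_fec=self.k_fec,
            fec_extent=self.fec_extent,
            scar_threshold=self.scar_threshold_mm,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfiguration:
    """Load a RunConfiguration from a YAML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    known = RunConfiguration.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "veins" in data:
        data["veins"] = tuple(data["veins"])
    cfg = RunConfiguration(**data)
    cfg.validate()
    return cfg


def build_subjects(config: RunConfiguration) -> list[Subject]:
    """Sample both cohorts and prepare coordinates, leads and RV electrodes."""
    subjects = []
    for cohort, n, base_seed in (("HF", config.n_hf, 0), ("RR", config.n_rr, 1)):
        if n == 0:
            continue
        spec = CohortSpecification(
            n_subjects=n,
            cohort_type=cohort,
            shape_coefficient_of_variation=config.shape_cv,
            random_seed=config.seed * 2 + base_seed,
        )
        spec = replace(
            spec,
            shape_mean=replace(
                spec.mean(), target_edge_length=config.target_edge_length
            ),
        )
        meshes = sample_cohort(spec)
        for i, mesh in enumerate(meshes):
            sid = f"{cohort}{i + 1:02d}"
            coords = compute_uvc(mesh)
            mesh = assign_rule_based_fibres(mesh, coords)
            aha = map_aha17(coords)
            leads = {}
            for vein in config.veins:
                line = locate_vein_line(
                    mesh, coords, aha, VEINS[vein], basal_z=config.basal_z
                )
                leads[vein] = place_electrodes(
                    mesh,
                    line,
                    n=config.n_electrodes,
                    spacing=config.electrode_spacing_mm,
                    basal_z=config.basal_z,
                )
            rv = place_rv_electrode(mesh, coords, config.rv_site)
            subjects.append(
                Subject(
                    subject_id=sid,
                    cohort=cohort,
                    mesh=mesh,
                    coords=coords,
                    leads=leads,
                    rv_node=rv,
                )
            )
            log.info("prepared subject %s (%d nodes, %d elements)", sid, mesh.n_nodes, mesh.n_elements)
    return subjects


def run_pipeline(config: RunConfiguration, subjects: Optional[Sequence[Subject]] = None) -> dict:
    """Run the full pipeline and write every artifact under the output dir.

    Returns a summary dict (also written as summary.json) with the campaign
    bookkeeping, per-cohort selections, statistics and file paths.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log.info("pipeline start (config %s)", chash)

    if subjects is None:
        subjects = build_subjects(config)
    params = config.conduction()
    matrix = run_campaign(subjects, params, config.veins)
    cio.write_response_csv(matrix, outdir / "response_matrix.csv")
    matrix.baselines.to_csv(outdir / "baselines.csv", index=False)

    cohorts = sorted({s.cohort for s in subjects})
    selections = {}
    for cohort in cohorts + (["RR+HF"] if len(cohorts) > 1 else []):
        sel = cohort_optimal(matrix, cohort)
        selections[cohort] = {
            "primary_design": sel.primary_design.name,
            "chosen_designs": [d.name for d in sel.chosen_designs],
            "per_subject_best": {
                s: {"vein": v, "config": c, "at090_red_pct": r}
                for s, (v, c, r) in sel.per_subject_best.items()
            },
        }

    # paired response test per cohort: are AT090 reductions > 0?
    tests = {}
    for cohort in cohorts:
        vals = matrix.records.query("cohort == @cohort")["at090_red_pct"]
        t = wilcoxon_signed_rank(vals.to_numpy())
        tests[cohort] = {
            "test": "wilcoxon_signed_rank",
            "statistic": t.statistic,
            "p_value": t.p_value,
            "n": t.n,
            "median_reduction_pct": t.effect_size,
        }

    summary = {
        "config": asdict(config),
        "config_hash": chash,
        "seed": config.seed,
        "bookkeeping": campaign_bookkeeping(
            len(subjects), n_veins=len(config.veins)
        ),
        "n_records": int(len(matrix.records)),
        "mean_at090_reduction_pct": float(matrix.records["at090_red_pct"].mean()),
        "selections": selections,
        "response_tests": tests,
    }

    if config.run_sensitivity:
        table, _ = run_oat_sensitivity(subjects, params, veins=config.veins)
        table.to_csv(outdir / "sensitivity.csv", index=False)
        summary["sensitivity"] = table.to_dict(orient="records")

    cio.write_manifest(summary, outdir / "summary.json")
    log.info("pipeline done: %d records", len(matrix.records))
    return summary
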