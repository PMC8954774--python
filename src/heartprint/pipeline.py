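"""End-to-end orchestration: simulate -> preprocess -> templates ->
identify / authenticate, with a run manifest for reproducibility auditing.

The session firewall is enforced structurally: every fitting step (classifier
training, ICA) consumes session-1 objects only; session-2 data is transformed
and scored but never fitted on.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import authenticate as auth
from . import identify as ident
from . import io as hio
from .preprocess import CycleTemplateSet, FilterSpec, extract_template_sets
from .synthetic import CohortSpec, ConfigurationError, ECGRecord, generate_cohort
from .templates import (
    ICAModel,
    MorseParams,
    SubjectFeatureMatrix,
    concatenate_subject_templates,
    fit_ica,
    scalogram_templates,
    transform_with_ica,
)

log = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """One end-to-end run over a synthetic cohort.

    ``identify_tasks`` entries: (methodology, classifier-or-None,
    configuration); ``authenticate_tasks`` entries: configuration strings.
    """

    cohort: CohortSpec = field(default_factory=CohortSpec)
    template_kind: str = "cycles"            # cycles | scalograms
    k: int = 20
    size: int = 56
    normalize: bool = True
    ica_components: int | None = 63
    identify_tasks: list[tuple] = field(default_factory=list)
    authenticate_tasks: list[str] = field(default_factory=list)
    out_dir: Path = Path("runs/default")
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        d["out_dir"] = str(self.out_dir)
        d["identify_tasks"] = [list(t) for t in self.identify_tasks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortSpec(**d["cohort"])
        if "out_dir" in d:
            d["out_dir"] = Path(d["out_dir"])
        if "identify_tasks" in d:
            d["identify_tasks"] = [tuple(t) for t in d["identify_tasks"]]
        return cls(**d)


@dataclass
class RunManifest:
    """Paths, digests and timestamps for every stage output."""

    config: dict
    version: str = __version__
    started: float = 0.0
    finished: float = 0.0
    artifacts: dict[str, dict] = field(default_factory=dict)

    def add(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.artifacts[name] = {"path": str(path), "sha256": digest}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def cohort_template_sets(
    records: list[ECGRecord],
    k_values: tuple[int, ...] = (20, 60),
    normalize: bool = True,
    filter_spec: FilterSpec = FilterSpec(),
) -> dict[int, dict[int, dict[str, CycleTemplateSet]]]:
    """Preprocess every record; returns sets[session][k][subject_id]."""
    out: dict[int, dict[int, dict[str, CycleTemplateSet]]] = {
        s: {k: {} for k in k_values} for s in (1, 2)
    }
    for rec in records:
        sets = extract_template_sets(rec, k_values, normalize=normalize,
                                     filter_spec=filter_spec)
        for k, tset in sets.items():
            out[rec.session_id][k][rec.subject_id] = tset
    return out


def cycle_feature_matrix(sets: dict[str, CycleTemplateSet]) -> SubjectFeatureMatrix:
    """Concatenate each subject's selected cycles into one feature row."""
    subjects = sorted(sets)
    m = concatenate_subject_templates({s: sets[s].cycles for s in subjects}, subjects)
    m.normalized = sets[subjects[0]].normalized
    return m


def scalogram_feature_matrix(sets: dict[str, CycleTemplateSet], fs: float,
                             size: int,
                             params: MorseParams = MorseParams()) -> SubjectFeatureMatrix:
    subjects = sorted(sets)
    imgs = {s: scalogram_templates(sets[s], fs, size, params) for s in subjects}
    m = concatenate_subject_templates(imgs, subjects)
    m.normalized = sets[subjects[0]].normalized
    return m


def three_block_test_matrices(sets60: dict[str, CycleTemplateSet]) -> list[SubjectFeatureMatrix]:
    """Three test templates per subject for Configuration 1/3: the 60
    selected session-2 cycles split into 3 consecutive blocks of 20, each
    concatenated."""
    subjects = sorted(sets60)
    out = []
    for b in range(3):
        block = {s: sets60[s].cycles[20 * b : 20 * (b + 1)] for s in subjects}
        m = concatenate_subject_templates(block, subjects)
        m.normalized = sets60[subjects[0]].normalized
        out.append(m)
    return out


def reduced_train_test(
    train: SubjectFeatureMatrix,
    tests: list[SubjectFeatureMatrix],
    n_components: int,
    seed: int,
) -> tuple[SubjectFeatureMatrix, list[SubjectFeatureMatrix], ICAModel]:
    """Fit ICA on the training matrix only; transform both sessions."""
    model = fit_ica(train, n_components=n_components, seed=seed)
    return transform_with_ica(train, model), [transform_with_ica(t, model) for t in tests], model


def run_pipeline(config: RunConfig) -> tuple[RunManifest, dict]:
    """Execute a full run and write all artifacts under ``config.out_dir``."""
    manifest = RunManifest(config=config.to_dict(), started=time.time())
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort_spec = dataclasses.replace(config.cohort, seed=config.seed)
    records = generate_cohort(cohort_spec)
    manifest_path = hio.write_cohort(records, out_dir / "cohort")
    manifest.add("cohort_manifest", manifest_path)

    needed_k = {config.k}
    for t in config.identify_tasks:
        if t[0] in ("classifier", "cnn"):
            needed_k.add(int(t[2].split("/")[0]))
    need_60 = any(cfg == "1/3" for cfg in config.authenticate_tasks) or any(
        t[0] == "distance" and t[2] == "1/3" for t in config.identify_tasks
    )
    if need_60:
        needed_k.add(60)
    k_values = sorted(needed_k)
    sets = cohort_template_sets(records, tuple(k_values), normalize=config.normalize)

    reports: dict[str, dict] = {}

    # classifier identification works on raw cycle sets
    for task in config.identify_tasks:
        methodology, clf, configuration = task
        if methodology == "classifier":
            cfg = ident.IdentConfig(methodology="classifier", classifier=clf,
                                    configuration=configuration,
                                    normalized=config.normalize, seed=config.seed)
            rep = ident.identify_with_classifier(sets[1][cfg.k], sets[2][cfg.k], cfg)
            name = f"identify_{clf}_{configuration.replace('/', '-')}"
            reports[name] = rep.to_dict()

    # distance arms need concatenated (and reduced) feature matrices
    distance_tasks = [t for t in config.identify_tasks if t[0] == "distance"]
    if distance_tasks or config.authenticate_tasks:
        if config.template_kind == "cycles":
            train_m = cycle_feature_matrix(sets[1][config.k])
            test_m = cycle_feature_matrix(sets[2][config.k])
        else:
            fs = records[0].fs
            train_m = scalogram_feature_matrix(sets[1][config.k], fs, config.size)
            test_m = scalogram_feature_matrix(sets[2][config.k], fs, config.size)
        tests3 = None
        if need_60 and config.template_kind == "cycles":
            tests3 = three_block_test_matrices(sets[2][60])
        if config.ica_components:
            all_tests = [test_m] + (tests3 or [])
            train_r, tests_r, _ = reduced_train_test(train_m, all_tests,
                                                     config.ica_components, config.seed)
            test_r, tests3_r = tests_r[0], tests_r[1:] or None
        else:
            train_r, test_r, tests3_r = train_m, test_m, tests3

        for task in distance_tasks:
            _, _, configuration = task
            cfg = ident.IdentConfig(methodology="distance", configuration=configuration,
                                    seed=config.seed)
            test_arg = test_r if configuration == "1/1" else tests3_r
            rep = ident.identify_with_distance(train_r, test_arg, cfg)
            reports[f"identify_distance_{configuration.replace('/', '-')}"] = rep.to_dict()

        for configuration in config.authenticate_tasks:
            test_arg = test_r if configuration == "1/1" else tests3_r
            if test_arg is None:
                raise ConfigurationError("Configuration 1/3 requires cycle templates")
            rep = auth.authenticate_cohort(train_r, test_arg, configuration)
            reports[f"authenticate_{configuration.replace('/', '-')}"] = rep.to_dict()

    for name, rep in reports.items():
        path = out_dir / f"{name}.json"
        hio.write_report(rep, path)
        manifest.add(name, path)

    manifest.finished = time.time()
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest, reports
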