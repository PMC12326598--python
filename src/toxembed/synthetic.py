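"""Seeded synthetic corpora with planted structure-activity signal.

Molecules are assembled from a curated inventory of ring cores and
substituents (guaranteeing chemical validity and scaffold diversity),
in vitro activities follow a logistic model on a sparse random subset of
fingerprint bits, and in vivo endpoints are noisy linear functions of the
latent in vitro activities — the exact transfer structure the
frozen-encoder protocol is meant to exploit.  Everything is reproducible
from a single seed.

The generator emulates the *statistical* shape of real assay panels
(sparse labels, low prevalence, label noise, dose/time readout tables);
it makes no attempt to match real potency distributions or readout units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chem
from .chem import DescriptorSet, Molecule
from .labels import EndpointStudy, SparseLabelMatrix, default_biochemistry_thresholds

# Ring cores with two substitution slots.  Every assembled string is
# re-validated with RDKit, so a pattern that yields an invalid SMILES for
# some substituent pair is simply skipped.
CORES: tuple[str, ...] = (
    "c1cc({0})ccc1{1}",          # benzene
    "c1cc({0})cnc1{1}",          # pyridine
    "c1cnc({0})nc1{1}",          # pyrimidine
    "c1csc({0})c1{1}",           # thiophene
    "c1coc({0})c1{1}",           # furan
    "c1c[nH]c({0})c1{1}",        # pyrrole
    "C1CCC({0})CC1{1}",          # cyclohexane
    "C1CC({0})CCN1{1}",          # piperidine
    "C1CC({0})CCO1",             # oxane (single slot)
    "c1ccc(-c2ccccc2{0})cc1{1}", # biphenyl
    "c1ccc2cc({0})ccc2c1",       # naphthalene (single slot)
    "C1CC1{0}",                  # cyclopropane (single slot)
    "O=C(N{0}){1}",              # amide (acyclic scaffold)
    "{0}CC(=O)O{1}",             # ester-ish chain (acyclic)
    "C1CCCC1{0}",                # cyclopentane
    "C1CCOC1{0}",                # oxolane
    "C1CCNC1{0}",                # pyrrolidine
    "C1CCSC1{0}",                # thiolane
    "C1CCCCCC1{0}",              # cycloheptane
    "c1ccoc1{0}",                # 2-substituted furan
    "c1ccsc1{0}",                # 2-substituted thiophene
    "C1COCCN1{0}",               # morpholine (N-substituted)
    "C1CCN(CC1){0}",             # piperidine (N-substituted)
    "C1CN(CCN1{0}){1}",          # piperazine
    "c1ccnc(c1){0}",             # 2-substituted pyridine
    "c1ccc2[nH]cc({0})c2c1",     # indole
    "c1ccc2occ({0})c2c1",        # benzofuran
    "c1ccc2scc({0})c2c1",        # benzothiophene
    "c1ccc(C2CCCC2{0})cc1",      # phenyl-cyclopentane, direct link
    "c1ccc(CC2CCCC2{0})cc1",     # ... one-carbon linker
    "c1ccc(CCC2CCCC2{0})cc1",    # ... two-carbon linker
    "c1ccc(C2CCNCC2{0})cc1",     # phenyl-piperidine
    "c1csc(C2CCCCC2{0})c1",      # thienyl-cyclohexane
    "c1ccc(CC2CCOC2{0})cc1",     # benzyl-oxolane
    "O=C1CCCN1{0}",              # pyrrolidinone
    "c1ccc(S(=O)(=O)N{0})cc1",   # benzenesulfonamide
)

SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CCCC", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "C#N", "C(=O)O", "C(=O)N", "C(=O)C",
    "S", "SC", "CO", "CN", "CCO", "CCN", "C=C", "CF", "CCl", "COC",
)

BIOCHEM_ENDPOINTS = ("ALT", "AST", "ALP", "GTP", "TC", "TG", "TBIL", "DBIL")


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic fixture bundle.

    Defaults mirror the desk-scale experiment: 2,000 molecules, 20 sparse
    in vitro assays at moderate prevalence, and 5 rare in vivo endpoints
    whose log-odds are coupled to the latent in vitro activities.
    """

    n_molecules: int = 2000
    n_invitro_tasks: int = 20
    n_invivo_tasks: int = 5
    invitro_prevalence: float = 0.15
    invivo_prevalence_range: tuple[float, float] = (0.02, 0.2)
    beta: float = 4.0  # weight scale of fingerprint bits on activity log-odds
    bits_per_task: int = 8
    planting_radius: int = 1  # circular-fingerprint radius of the planted bits
    planting_freq_window: tuple[float, float] = (0.05, 0.95)
    label_noise: float = 0.05
    invitro_missing_rate: float = 0.3
    invivo_missing_rate: float = 0.0
    coupling: float = 1.0  # in vitro -> in vivo signal strength
    couplings_per_task: int = 5
    invivo_noise_sd: float = 0.5
    descriptor_names: tuple[str, ...] = tuple(chem.QUICK_DESCRIPTORS)
    doses: tuple[float, ...] = (10.0, 30.0, 100.0)
    times: tuple[float, ...] = (4.0, 8.0, 24.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.invitro_prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        lo, hi = self.invivo_prevalence_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("in vivo prevalence range must lie in (0, 1)")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label noise rate must lie in [0, 0.5)")


@dataclass
class SyntheticCorpus:
    """A generated corpus with its planted ground truth."""

    spec: SyntheticSpec
    molecules: list[Molecule]
    fingerprints: np.ndarray  # N x 1024, the standard diameter-6 representation
    planting_fingerprints: np.ndarray  # N x 1024 at the planting radius
    descriptors: DescriptorSet
    invitro: SparseLabelMatrix
    latents: np.ndarray  # N x P_invitro pre-threshold activity scores
    task_bits: list[np.ndarray]  # indices into planting_fingerprints
    task_weights: list[np.ndarray]


def _assemble_molecules(spec: SyntheticSpec, rng: np.random.Generator) -> list[Molecule]:
    seen: set[str] = set()
    out: list[Molecule] = []
    attempts = 0
    max_attempts = 400 * spec.n_molecules
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"fragment inventory exhausted after {attempts} attempts "
                f"({len(out)}/{spec.n_molecules} molecules)"
            )
        core = CORES[rng.integers(len(CORES))]
        subs = [SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))] for _ in range(2)]
        try:
            raw = core.format(*subs)
        except IndexError:  # pragma: no cover - single-slot formats take one
            raw = core.format(subs[0])
        canonical = chem.canonicalize(raw)
        if canonical is None or canonical in seen:
            continue
        kept, _ = chem.preprocess([canonical])
        if not kept:
            continue
        seen.add(canonical)
        out.append(kept[0])
    return out


def _calibrated_labels(
    scores: np.ndarray, target: float, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli labels whose realized prevalence lands on ``target``.

    The logistic intercept is bisected against the realized draw (one
    uniform per molecule, reused across bisection steps, so the count is
    monotone in the intercept); noise then flips an exact fraction of each
    class, which the pre-noise target compensates for.
    """
    n = scores.shape[0]
    pre_target = (target - noise) / (1.0 - 2.0 * noise)
    if not 0.0 < pre_target < 1.0:
        raise ValueError(
            f"prevalence {target} unreachable under label noise {noise}"
        )
    u = rng.random(n)
    want = int(round(pre_target * n))
    lo, hi = -30.0, 30.0
    labels = None
    for _ in range(80):
        c = 0.5 * (lo + hi)
        p = 1.0 / (1.0 + np.exp(-(scores + c)))
        labels = (u < p).astype(np.float64)
        count = int(labels.sum())
        if count < want:
            lo = c
        elif count > want:
            hi = c
        else:
            break
    if noise > 0:
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        flip_pos = rng.choice(pos, size=int(round(noise * pos.size)), replace=False)
        flip_neg = rng.choice(neg, size=int(round(noise * neg.size)), replace=False)
        labels[flip_pos] = 0.0
        labels[flip_neg] = 1.0
    return labels


def _stratified_missing(
    labels: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Hide ``rate`` of each class so observed prevalence tracks the target."""
    out = labels.astype(np.float64).copy()
    if rate <= 0:
        return out
    for value in (0.0, 1.0):
        idx = np.flatnonzero(labels == value)
        hide = rng.choice(idx, size=int(round(rate * idx.size)), replace=False)
        out[hide] = np.nan
    return out


def generate_corpus(spec: SyntheticSpec | None = None) -> SyntheticCorpus:
    """Molecules, descriptor targets and a planted-signal in vitro panel."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    molecules = _assemble_molecules(spec, rng)
    fingerprints = chem.fingerprint_matrix(molecules)
    planting = (
        fingerprints
        if spec.planting_radius == chem.FINGERPRINT_RADIUS
        else chem.fingerprint_matrix(molecules, radius=spec.planting_radius)
    )
    descriptors = chem.descriptors(molecules, names=list(spec.descriptor_names))

    # plant on bits that are common enough to recur across scaffolds
    lo, hi = spec.planting_freq_window
    bit_freq = planting.mean(axis=0)
    informative = np.flatnonzero((bit_freq > lo) & (bit_freq < hi))
    if informative.size < spec.bits_per_task:
        raise ValueError("corpus too homogeneous: not enough varying fingerprint bits")

    values = np.empty((spec.n_molecules, spec.n_invitro_tasks))
    latents = np.empty_like(values)
    task_bits, task_weights = [], []
    for p in range(spec.n_invitro_tasks):
        bits = rng.choice(informative, size=spec.bits_per_task, replace=False)
        w = spec.beta * rng.normal(size=spec.bits_per_task)
        score = planting[:, bits].astype(np.float64) @ w
        latents[:, p] = score
        labels = _calibrated_labels(score, spec.invitro_prevalence, spec.label_noise, rng)
        values[:, p] = _stratified_missing(labels, spec.invitro_missing_rate, rng)
        task_bits.append(bits)
        task_weights.append(w)
    invitro = SparseLabelMatrix(
        values,
        [f"assay_{p:03d}" for p in range(spec.n_invitro_tasks)],
        [m.canonical_smiles for m in molecules],
    )
    return SyntheticCorpus(
        spec=spec,
        molecules=molecules,
        fingerprints=fingerprints,
        planting_fingerprints=planting,
        descriptors=descriptors,
        invitro=invitro,
        latents=latents,
        task_bits=task_bits,
        task_weights=task_weights,
    )


@dataclass
class SyntheticStudy:
    """In vivo endpoint labels plus the dose/time readout table behind them."""

    invivo: SparseLabelMatrix
    study: EndpointStudy
    logits: np.ndarray  # N x P_invivo pre-threshold log-odds
    coupling_matrix: np.ndarray


def generate_invivo_study(
    corpus: SyntheticCorpus, spec: SyntheticSpec | None = None
) -> SyntheticStudy:
    """Endpoints coupled to the latent in vitro activities.

    Each in vivo task's log-odds is a coupling-weighted sum of a few
    standardized latent activities plus Gaussian noise, thresholded at
    the task's prevalence quantile.  A dose/time readout table is emitted
    whose any-exceedance binarization reproduces the labels exactly.
    """
    spec = spec or corpus.spec
    rng = np.random.default_rng(spec.seed + 101)
    n = len(corpus.molecules)
    z = corpus.latents
    z = (z - z.mean(axis=0)) / np.maximum(z.std(axis=0), 1e-9)

    n_tasks = spec.n_invivo_tasks
    coupling_matrix = np.zeros((n_tasks, spec.n_invitro_tasks))
    for t in range(n_tasks):
        cols = rng.choice(
            spec.n_invitro_tasks,
            size=min(spec.couplings_per_task, spec.n_invitro_tasks),
            replace=False,
        )
        coupling_matrix[t, cols] = rng.normal(size=cols.size)
    signal = z @ coupling_matrix.T
    signal = signal / np.maximum(signal.std(axis=0), 1e-9)
    logits = spec.coupling * signal + spec.invivo_noise_sd * rng.normal(size=(n, n_tasks))

    lo, hi = spec.invivo_prevalence_range
    prevalences = np.linspace(lo, hi, n_tasks)
    values = np.empty((n, n_tasks))
    for t in range(n_tasks):
        cutoff = np.quantile(logits[:, t], 1.0 - prevalences[t])
        values[:, t] = (logits[:, t] > cutoff).astype(np.float64)
        values[:, t] = _stratified_missing(values[:, t], spec.invivo_missing_rate, rng)

    endpoints = [BIOCHEM_ENDPOINTS[t % len(BIOCHEM_ENDPOINTS)] for t in range(n_tasks)]
    if len(set(endpoints)) < n_tasks:  # more tasks than endpoint names
        endpoints = [f"{e}_{t}" for t, e in enumerate(endpoints)]
    thresholds_all = default_biochemistry_thresholds()
    thresholds = {
        e: thresholds_all.get(e.split("_")[0], 2.0) for e in endpoints
    }
    invivo = SparseLabelMatrix(
        values, endpoints, [m.canonical_smiles for m in corpus.molecules]
    )

    records = []
    mols = [m.canonical_smiles for m in corpus.molecules]
    for t, ep in enumerate(endpoints):
        th = thresholds[ep]
        for i in range(n):
            label = values[i, t]
            if np.isnan(label):
                continue
            grid = [(d, h) for d in spec.doses for h in spec.times]
            exceed_at = rng.integers(len(grid)) if label == 1.0 else -1
            for g, (dose, time) in enumerate(grid):
                if g == exceed_at:
                    value = th * rng.uniform(1.2, 3.0)
                else:
                    value = th * rng.uniform(0.2, 0.95)
                records.append((mols[i], ep, dose, time, value))
    study = EndpointStudy(
        pd.DataFrame(records, columns=["molecule", "endpoint", "dose", "time", "value"]),
        thresholds,
    )
    return SyntheticStudy(
        invivo=invivo, study=study, logits=logits, coupling_matrix=coupling_matrix
    )


def write_bundle(
    corpus: SyntheticCorpus,
    study: SyntheticStudy,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the full fixture bundle as plain-text CSV/YAML files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": out / "corpus.csv",
        "invitro": out / "invitro.csv",
        "invivo": out / "invivo.csv",
        "readouts": out / "readouts.csv",
        "spec": out / "spec.yaml",
    }
    pd.DataFrame(
        {
            "smiles": [m.canonical_smiles for m in corpus.molecules],
            "scaffold": [m.scaffold_key for m in corpus.molecules],
        }
    ).to_csv(paths["corpus"], index=False)
    corpus.invitro.to_csv(paths["invitro"])
    study.invivo.to_csv(paths["invivo"])
    study.study.to_csv(paths["readouts"])
    spec_dict = asdict(corpus.spec)
    spec_dict["descriptor_names"] = list(spec_dict["descriptor_names"])
    for key in ("invivo_prevalence_range", "planting_freq_window", "doses", "times"):
        spec_dict[key] = list(spec_dict[key])
    paths["spec"].write_text(yaml.safe_dump(spec_dict, sort_keys=True))
    return paths
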