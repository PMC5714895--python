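"""Synthetic replicated multi-genotype time-course count datasets.

The generator emulates the study design the pipeline targets: 4 genotypes
(two mutant / non-mutant pairs) x 5 developmental stages x 3 replicates,
with planted co-expression modules, planted TF regulators, planted
mutant-specific perturbations, and a planted GO term per module.

Generating model (log2 latent scale):

* Each module m has a stage trend f_m shared by all genotypes: a free
  per-stage profile, drawn i.i.d. normal, centered, and scaled to peak
  amplitude effect_sd log2 units (with only a handful of stages, any
  polynomial parameterization collapses onto one or two effective shape
  dimensions; free profiles span the whole centered curve space and keep
  planted modules mutually distinguishable).  Bounding the amplitude
  keeps module troughs well above zero counts, so the log2(FPKM+1)
  transform downstream stays effectively affine for every gene.  Trends
  are redrawn until every pair of accepted trends has |Pearson r| <=
  max_profile_cor and each trend moves by at least min_stage_step log2
  units between some adjacent stages, so modules are separable and their
  members are detectable as between-stage DE.
* A fraction of modules is perturbed: in one designated mutant genotype
  their latent profile is shifted by +/- mutant_shift at every stage.
  Stage-wise true-DE sets are therefore exactly the perturbed-module
  member genes.
* Member genes: log2 mean = b_g + a_g * L_m(genotype, stage), with
  baseline b_g ~ N(base_log2_mean, base_log2_sd) and amplitude
  a_g ~ U(amplitude_range).
* Regulator TFs track their module's base trend f_m (not the mutant
  shift) with unit coupling plus small per-stage jitter (shared across
  genotypes, so TFs are never spuriously mutant-vs-partner DE and the
  stage-wise truth stays exact); remaining
  (bystander) TFs follow independent random stage trends, rejected to
  |Pearson r| <= max_profile_cor against every module trend — the same
  identifiability condition imposed between module trends: a bystander
  whose chance correlation with a module rivals the planted regulator's
  coupling would make the planted edge set unrecoverable by any method.
  Noise genes are flat.
* Counts ~ NB(mean = 2^log2mean * library factor, dispersion) via the
  gamma-Poisson mixture; library factors ~ U(library_size_range).

Everything is driven by one integer seed; a fixed seed gives byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression_io import (
    MUTANT,
    NON_MUTANT,
    ExpressionMatrix,
    GeneAnnotation,
    SampleDesign,
)


@dataclass
class SimulationConfig:
    n_stages: int = 5
    n_reps: int = 3
    genotype_pairs: tuple[tuple[str, str], ...] = (("3mlpa", "3MWT"), ("1mlpa", "1MWT"))
    n_modules: int = 10
    genes_per_module: int = 50
    n_tfs: int = 60
    regulators_per_module: tuple[int, int] = (1, 2)
    n_noise_genes: int = 500
    effect_sd: float = 2.8  # peak trend amplitude, log2 units
    reg_noise_sd: float = 0.25  # per-stage jitter on TF profiles (shared across genotypes)
    amplitude_range: tuple[float, float] = (0.9, 1.1)  # member-gene coupling to the latent
    noise_dispersion: float = 0.1  # NB dispersion (var = mu + disp * mu^2)
    library_size_range: tuple[float, float] = (0.7, 1.3)
    de_fraction_mutant: float = 0.4  # fraction of modules perturbed in a mutant
    mutant_shift: float = 3.0  # log2 shift of perturbed modules in mutants
    base_log2_mean: float = 8.0
    base_log2_sd: float = 0.8
    max_profile_cor: float = 0.75
    min_stage_step: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regulators_per_module[1] * self.n_modules > self.n_tfs:
            raise ValueError("more regulators requested than TFs available")
        if self.n_stages < 2 or self.n_reps < 1 or self.n_modules < 1:
            raise ValueError("infeasible design sizes")

    @property
    def n_genotypes(self) -> int:
        return 2 * len(self.genotype_pairs)

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(self.n_stages))

    @property
    def genotypes(self) -> tuple[str, ...]:
        return tuple(g for pair in self.genotype_pairs for g in pair)


@dataclass
class GroundTruth:
    """The generating process, exposed for evaluation."""

    module_assignment: dict[str, int]  # signal gene -> module id (1-based)
    edges: set[tuple[str, int]]  # (regulator TF, module id)
    true_log2_mean: pd.DataFrame  # gene x condition latent means
    stagewise_de: dict[str, set[str]]  # stage-wise contrast label -> true DE genes
    go_term_of_module: dict[int, str]
    perturbed_modules: dict[int, str]  # module id -> mutant genotype carrying the shift

    def true_de_set(self, label_a: tuple[str, str], label_b: tuple[str, str], lfc_min: float = 1.0) -> set[str]:
        """Genes whose latent log2 means differ by > lfc_min between two conditions."""
        a = self.true_log2_mean[f"{label_a[0]}:{label_a[1]}"]
        b = self.true_log2_mean[f"{label_b[0]}:{label_b[1]}"]
        diff = (a - b).abs()
        return set(diff.index[diff > lfc_min])


def _module_trends(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Mutually decorrelated random stage trends, shape (modules, stages).

    Each trend must step by >= min_stage_step between some adjacent
    stages, and must have |Pearson r| <= max_profile_cor with all
    previously accepted trends.
    """
    trends: list[np.ndarray] = []
    attempts = 0
    while len(trends) < cfg.n_modules:
        f = rng.normal(0.0, 1.0, size=cfg.n_stages)
        f = f - f.mean()
        peak = np.max(np.abs(f))
        if peak == 0:
            continue
        f = f * (cfg.effect_sd / peak)
        attempts += 1
        if attempts > 500 * cfg.n_modules:
            raise RuntimeError("could not draw decorrelated module trends; relax config")
        if np.max(np.abs(np.diff(f))) < cfg.min_stage_step:
            continue
        ok = True
        for g in trends:
            r = np.corrcoef(f, g)[0, 1]
            if abs(r) > cfg.max_profile_cor:
                ok = False
                break
        if ok:
            trends.append(f)
    return np.stack(trends)


def simulate_dataset(
    cfg: SimulationConfig | None = None,
) -> tuple[ExpressionMatrix, SampleDesign, GeneAnnotation, GroundTruth]:
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    stages = cfg.stages
    genotypes = cfg.genotypes
    conditions = [(g, s) for g in genotypes for s in stages]
    cond_labels = [f"{g}:{s}" for g, s in conditions]
    mutants = [m for m, _ in cfg.genotype_pairs]

    trends = _module_trends(rng, cfg)  # n_modules x n_stages

    # which modules are perturbed, and in which mutant genotype
    n_pert = int(round(cfg.de_fraction_mutant * cfg.n_modules))
    pert_ids = rng.choice(cfg.n_modules, size=n_pert, replace=False)
    perturbed: dict[int, str] = {}
    signs: dict[int, float] = {}
    for i, mod in enumerate(sorted(int(m) + 1 for m in pert_ids)):
        perturbed[mod] = mutants[i % len(mutants)]
        signs[mod] = float(rng.choice([-1.0, 1.0]))

    # latent module profile over all conditions
    latent = np.zeros((cfg.n_modules, len(conditions)))
    for m in range(cfg.n_modules):
        mod = m + 1
        for c, (g, s) in enumerate(conditions):
            val = trends[m, stages.index(s)]
            if mod in perturbed and g == perturbed[mod]:
                val += signs[mod] * cfg.mutant_shift
            latent[m, c] = val

    # regulator assignment: first TFs act as regulators, rest are bystanders
    lo, hi = cfg.regulators_per_module
    edges: set[tuple[str, int]] = set()
    tf_ids = [f"TF{i:03d}" for i in range(cfg.n_tfs)]
    next_tf = 0
    regulator_of: dict[str, int] = {}
    for m in range(cfg.n_modules):
        n_reg = int(rng.integers(lo, hi + 1))
        for _ in range(n_reg):
            tf = tf_ids[next_tf]
            next_tf += 1
            regulator_of[tf] = m + 1
            edges.add((tf, m + 1))

    gene_rows: list[str] = []
    mean_rows: list[np.ndarray] = []
    assignment: dict[str, int] = {}

    # module member genes
    for m in range(cfg.n_modules):
        mod = m + 1
        for i in range(cfg.genes_per_module):
            gid = f"M{mod:02d}G{i:03d}"
            b = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd)
            a = rng.uniform(*cfg.amplitude_range)
            gene_rows.append(gid)
            mean_rows.append(b + a * latent[m])
            assignment[gid] = mod

    # TFs: regulators track their module's base trend; others free cubics
    base_trend_by_cond = np.zeros((cfg.n_modules, len(conditions)))
    for m in range(cfg.n_modules):
        for c, (_, s) in enumerate(conditions):
            base_trend_by_cond[m, c] = trends[m, stages.index(s)]
    for tf in tf_ids:
        b = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd)
        if tf in regulator_of:
            m = regulator_of[tf] - 1
            jit = rng.normal(0.0, cfg.reg_noise_sd, cfg.n_stages)
            prof = base_trend_by_cond[m] + np.array(
                [jit[stages.index(s_)] for _, s_ in conditions]
            )
        else:
            # bystander TFs vary across stages (realistic DE background) but
            # are decorrelated from module trends so the planted regulators
            # stay identifiable
            for _ in range(500):
                f = rng.normal(0.0, 1.0, size=cfg.n_stages)
                f = f - f.mean()
                peak = np.max(np.abs(f))
                if peak == 0:
                    continue
                f = f * (cfg.effect_sd / peak)
                if all(
                    abs(np.corrcoef(f, trends[m])[0, 1]) <= cfg.max_profile_cor
                    for m in range(cfg.n_modules)
                ):
                    break
            jit = rng.normal(0.0, cfg.reg_noise_sd, cfg.n_stages)
            prof = np.array([f[stages.index(s_)] + jit[stages.index(s_)] for _, s_ in conditions])
        gene_rows.append(tf)
        mean_rows.append(b + prof)

    # flat noise genes
    for i in range(cfg.n_noise_genes):
        gid = f"NS{i:04d}"
        b = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd)
        gene_rows.append(gid)
        mean_rows.append(np.full(len(conditions), b))

    true_log2 = pd.DataFrame(np.stack(mean_rows), index=gene_rows, columns=cond_labels)

    # sample design
    design_rows = []
    for pair in cfg.genotype_pairs:
        for geno in pair:
            is_mut = geno == pair[0]
            partner = pair[1] if is_mut else pair[0]
            for s in stages:
                for r in range(1, cfg.n_reps + 1):
                    design_rows.append(
                        {
                            "sample_id": f"{geno}_{s}_r{r}",
                            "genotype": geno,
                            "stage": s,
                            "replicate": r,
                            "genotype_class": MUTANT if is_mut else NON_MUTANT,
                            "mutant_partner": partner,
                        }
                    )
    design = SampleDesign(pd.DataFrame(design_rows), stages=stages)

    # counts: NB via gamma-Poisson, library factor per sample
    lib = rng.uniform(*cfg.library_size_range, size=len(design.sample_ids))
    mu_cond = 2.0 ** true_log2.to_numpy()
    counts = np.zeros((len(gene_rows), len(design.sample_ids)), dtype=np.int64)
    for j, sid in enumerate(design.sample_ids):
        geno = design.table.loc[sid, "genotype"]
        stage = design.table.loc[sid, "stage"]
        c = cond_labels.index(f"{geno}:{stage}")
        mu = mu_cond[:, c] * lib[j]
        if cfg.noise_dispersion > 0:
            shape = 1.0 / cfg.noise_dispersion
            lam = rng.gamma(shape, mu * cfg.noise_dispersion)
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)
    em = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_rows, columns=design.sample_ids), scale="raw_counts"
    )

    # annotation: lengths, TF list, GO map (one planted term per module + background)
    lengths = {g: float(rng.integers(500, 5001)) for g in gene_rows}
    go_map: dict[str, set[str]] = {}
    go_term_of_module = {m + 1: f"GO:90{m + 1:05d}" for m in range(cfg.n_modules)}
    for gid, mod in assignment.items():
        go_map.setdefault(gid, set()).add(go_term_of_module[mod])
    all_genes = list(gene_rows)
    for b_term in range(20):
        term = f"GO:80{b_term:05d}"
        for g in rng.choice(all_genes, size=30, replace=False):
            go_map.setdefault(str(g), set()).add(term)
    ann = GeneAnnotation(tf_genes=set(tf_ids), go_map=go_map, gene_lengths=lengths)

    # stage-wise true-DE sets: exactly the perturbed-module members
    stagewise_de: dict[str, set[str]] = {}
    for mut, wt in cfg.genotype_pairs:
        genes = {
            g for g, mod in assignment.items() if mod in perturbed and perturbed[mod] == mut
        }
        for s in stages:
            stagewise_de[f"{mut}_vs_{wt}.{s}"] = set(genes)

    truth = GroundTruth(
        module_assignment=assignment,
        edges=edges,
        true_log2_mean=true_log2,
        stagewise_de=stagewise_de,
        go_term_of_module=go_term_of_module,
        perturbed_modules=perturbed,
    )
    return em, design, ann, truth


def write_dataset(
    dataset: tuple[ExpressionMatrix, SampleDesign, GeneAnnotation, GroundTruth],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write counts.tsv, design.tsv, lengths.tsv, tfs.txt, go_map.tsv, truth/."""
    em, design, ann, truth = dataset
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    paths["counts"] = outdir / "counts.tsv"
    em.data.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    paths["design"] = outdir / "design.tsv"
    design.table.reset_index().to_csv(paths["design"], sep="\t", index=False)
    paths["lengths"] = outdir / "lengths.tsv"
    pd.DataFrame(
        {"gene_id": list(ann.gene_lengths), "length_bp": [int(v) for v in ann.gene_lengths.values()]}
    ).to_csv(paths["lengths"], sep="\t", index=False)
    paths["tfs"] = outdir / "tfs.txt"
    paths["tfs"].write_text("\n".join(sorted(ann.tf_genes)) + "\n")
    paths["go_map"] = outdir / "go_map.tsv"
    with open(paths["go_map"], "w") as fh:
        for g in sorted(ann.go_map):
            for t in sorted(ann.go_map[g]):
                fh.write(f"{g}\t{t}\n")

    paths["truth_modules"] = truth_dir / "modules.tsv"
    pd.DataFrame(
        {"gene_id": list(truth.module_assignment), "module_id": list(truth.module_assignment.values())}
    ).to_csv(paths["truth_modules"], sep="\t", index=False)
    paths["truth_edges"] = truth_dir / "edges.tsv"
    pd.DataFrame(sorted(truth.edges), columns=["tf", "module_id"]).to_csv(
        paths["truth_edges"], sep="\t", index=False
    )
    paths["truth_stagewise_de"] = truth_dir / "stagewise_de.tsv"
    with open(paths["truth_stagewise_de"], "w") as fh:
        fh.write("contrast_label\tgene_id\n")
        for label in sorted(truth.stagewise_de):
            for g in sorted(truth.stagewise_de[label]):
                fh.write(f"{label}\t{g}\n")
    return paths


def simulate_two_group(
    n_genes: int = 2000,
    n_planted: int = 0,
    lfc: float = 0.0,
    mu_log2: float = 8.0,
    dispersion: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleDesign, list[str]]:
    """Single-contrast calibration dataset: two groups, optional planted effect.

    The first ``n_planted`` genes carry a +/- ``lfc`` log2 shift in the
    mutant group; everything else is null.  Returns the raw count matrix,
    a one-stage two-genotype design, and the planted gene IDs.  Used for
    false-positive-rate and sensitivity calibration of the DE stage.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(mu_log2, 0.5, n_genes)
    eff = np.zeros(n_genes)
    if n_planted:
        eff[:n_planted] = lfc * rng.choice([-1.0, 1.0], n_planted)
    mu_a = 2.0 ** (base + eff)
    mu_b = 2.0**base

    def nb(mu: np.ndarray) -> np.ndarray:
        means = np.outer(mu, np.ones(n_reps))
        if dispersion > 0:
            lam = rng.gamma(1.0 / dispersion, means * dispersion)
        else:
            lam = means
        return rng.poisson(lam)

    genes = [f"g{i:05d}" for i in range(n_genes)]
    cols = [f"mutX_S1_r{r}" for r in range(1, n_reps + 1)] + [
        f"wtX_S1_r{r}" for r in range(1, n_reps + 1)
    ]
    rows = [
        {
            "sample_id": c,
            "genotype": "mutX" if c.startswith("mut") else "wtX",
            "stage": "S1",
            "replicate": int(c.rsplit("r", 1)[1]),
            "genotype_class": MUTANT if c.startswith("mut") else NON_MUTANT,
            "mutant_partner": "wtX" if c.startswith("mut") else "mutX",
        }
        for c in cols
    ]
    design = SampleDesign(pd.DataFrame(rows), stages=("S1",))
    em = ExpressionMatrix(
        pd.DataFrame(np.hstack([nb(mu_a), nb(mu_b)]), index=genes, columns=cols),
        scale="raw_counts",
    )
    return em, design, genes[:n_planted]
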