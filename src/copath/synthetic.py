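"""Synthetic negative-binomial count data with planted path structure.

The generator emulates a four-condition injury/treatment design: a
never-injured reference given vehicle, the same tissue given the drug,
an injured group given vehicle, and an injured group given the drug.
Each gene is assigned a trajectory class — for example "upregulated by
injury, restored to baseline by the drug" — which fixes its planted log2
fold change in every non-reference condition. Counts are drawn from a
negative binomial with variance mu + alpha * mu^2, the standard RNA-seq
mean-dispersion convention, under per-sample sequencing-depth factors.
Gene-set terms can be planted into a class so that enrichment recovery
is testable against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountDataset, ExperimentDesign, GeneSetCollection
from .errors import SimulationSpecError

#: Default condition labels: non-injured/injured x vehicle/drug.
DEFAULT_CONDITIONS = ("NI_vehicle", "NI_C286", "SNL_vehicle", "SNL_C286")

#: Sign pattern of the planted effect over the non-reference conditions,
#: in DEFAULT_CONDITIONS order (drug alone, injury alone, injury + drug).
#: "restored" classes return to 0 under the drug; "persistent" classes do
#: not; "drug_only" classes respond to the drug wherever it is given.
PATH_CLASS_SIGNS: dict[str, tuple[int, int, int]] = {
    "up_injury_restored": (0, +1, 0),
    "down_injury_restored": (0, -1, 0),
    "up_injury_persistent": (0, +1, +1),
    "down_injury_persistent": (0, -1, -1),
    "drug_only_up": (+1, 0, +1),
    "drug_only_down": (-1, 0, -1),
    "flat": (0, 0, 0),
}


def planted_path_classes() -> list[str]:
    """Ordered labels of the trajectory classes the generator can plant."""
    return list(PATH_CLASS_SIGNS)


def _default_path_fractions() -> dict[str, float]:
    return {c: 0.05 for c in planted_path_classes() if c != "flat"}


def _default_planted_enrichment() -> dict[str, tuple[str, float]]:
    non_flat = [c for c in planted_path_classes() if c != "flat"]
    return {c: (f"T{i + 1:04d}", 0.6) for i, c in enumerate(non_flat)}


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic dataset.

    Attributes
    ----------
    n_genes
        Number of simulated genes.
    conditions
        Ordered condition labels; the first is the reference.
    n_replicates
        Biological replicates per condition.
    baseline_mean_log2_range
        Per-gene baseline expression b_g ~ Uniform over this log2 range,
        i.e. mean counts 2**low .. 2**high at unit depth.
    dispersion
        NB dispersion alpha in var = mu + alpha * mu**2; alpha -> 0 is the
        Poisson limit.
    effect_log2fc
        Magnitude of every planted fold change, in log2 units.
    path_fractions
        Trajectory class -> fraction of genes planted in it; the
        remainder of the genes are flat. Fractions must sum to <= 1.
    library_size_factor_range
        Per-sample depth multipliers, drawn log-uniformly.
    n_terms
        Number of gene-set terms to generate.
    term_size_range
        Inclusive range of term sizes.
    planted_enrichment
        Trajectory class -> (term ID, fraction of that term's genes drawn
        from the class). Terms not named here are uniform draws.
    seed
        Seed for the single random generator driving the simulation.
    """

    n_genes: int = 10_000
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_replicates: int = 4
    baseline_mean_log2_range: tuple[float, float] = (5.0, 10.0)
    dispersion: float = 0.05
    effect_log2fc: float = 2.0
    path_fractions: dict[str, float] = field(default_factory=_default_path_fractions)
    library_size_factor_range: tuple[float, float] = (0.5, 2.0)
    n_terms: int = 200
    term_size_range: tuple[int, int] = (20, 100)
    planted_enrichment: dict[str, tuple[str, float]] = field(
        default_factory=_default_planted_enrichment
    )
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.n_genes < 1:
            raise SimulationSpecError("n_genes must be positive")
        if self.n_replicates < 1:
            raise SimulationSpecError("n_replicates must be positive")
        if len(self.conditions) < 2:
            raise SimulationSpecError("need a reference plus >= 1 condition")
        if len(set(self.conditions)) != len(self.conditions):
            raise SimulationSpecError("condition labels must be unique")
        if self.dispersion <= 0:
            raise SimulationSpecError("dispersion must be > 0")
        if self.effect_log2fc < 0:
            raise SimulationSpecError("effect_log2fc must be >= 0")
        for name in (
            "baseline_mean_log2_range",
            "library_size_factor_range",
            "term_size_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise SimulationSpecError(f"{name}: low {lo} > high {hi}")
        lo, _ = self.library_size_factor_range
        if lo <= 0:
            raise SimulationSpecError("library size factors must be positive")
        unknown = set(self.path_fractions) - set(PATH_CLASS_SIGNS)
        if unknown:
            raise SimulationSpecError(f"unknown path classes: {sorted(unknown)}")
        if "flat" in self.path_fractions:
            raise SimulationSpecError(
                "flat is the remainder class; do not list it in path_fractions"
            )
        if any(f < 0 for f in self.path_fractions.values()):
            raise SimulationSpecError("path fractions must be >= 0")
        total = sum(self.path_fractions.values())
        if total > 1 + 1e-12:
            raise SimulationSpecError(
                f"path fractions sum to {total:.4g} > 1"
            )
        for cls, (term, frac) in self.planted_enrichment.items():
            if cls not in PATH_CLASS_SIGNS or cls == "flat":
                raise SimulationSpecError(
                    f"planted_enrichment targets unknown class {cls!r}"
                )
            if not (0 <= frac <= 1):
                raise SimulationSpecError(
                    f"planted fraction for term {term!r} must be in [0, 1]"
                )
            index = int(term[1:]) if term[1:].isdigit() else 0
            if not (term.startswith("T") and 1 <= index <= self.n_terms):
                raise SimulationSpecError(
                    f"planted term {term!r} outside the generated ID range "
                    f"T0001..T{self.n_terms:04d}"
                )

    @property
    def design(self) -> ExperimentDesign:
        return ExperimentDesign(
            reference_condition=self.conditions[0],
            path_conditions=self.conditions[1:],
        )

    def class_deltas(self, path_class: str) -> dict[str, float]:
        """Planted log2 effect per non-reference condition for one class."""
        signs = PATH_CLASS_SIGNS[path_class]
        non_ref = self.conditions[1:]
        if len(signs) != len(non_ref):
            raise SimulationSpecError(
                "planted class patterns are defined for exactly "
                f"{len(signs)} non-reference conditions, got {len(non_ref)}"
            )
        return {c: s * self.effect_log2fc for c, s in zip(non_ref, signs)}

    def expected_path_label(self, path_class: str) -> tuple[str, ...]:
        """The call tuple a perfectly recovered gene of this class gets."""
        deltas = self.class_deltas(path_class)
        return tuple(
            "up" if d > 0 else "down" if d < 0 else "unchanged"
            for d in (deltas[c] for c in self.conditions[1:])
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth manifest of one simulated dataset.

    ``gene_truth`` has one row per gene: its trajectory class and planted
    log2 fold change in each non-reference condition. ``term_truth`` has
    one row per term: whether enrichment was planted, into which class,
    and at what fraction.
    """

    gene_truth: pd.DataFrame
    term_truth: pd.DataFrame
    spec: SimulationSpec

    def genes_in_class(self, path_class: str) -> frozenset[str]:
        mask = self.gene_truth["path_class"] == path_class
        return frozenset(self.gene_truth.loc[mask, "gene"])

    def planted_terms(self) -> pd.DataFrame:
        return self.term_truth[self.term_truth["planted"]]


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[CountDataset, GeneSetCollection, SyntheticTruth]:
    """Draw one dataset, its gene-set annotation, and the truth manifest.

    Counts are NB with mean ``2**(b_g + delta_gc) * s_s`` where ``b_g`` is
    the gene's baseline log2 mean, ``delta_gc`` the planted effect in
    sample *s*'s condition (0 in the reference), and ``s_s`` the sample's
    depth factor. The same seed always yields byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)

    width = max(5, len(str(spec.n_genes)))
    genes = [f"g{i + 1:0{width}d}" for i in range(spec.n_genes)]

    # Class assignment: deterministic counts per class, random placement.
    classes = np.array(["flat"] * spec.n_genes, dtype=object)
    order = rng.permutation(spec.n_genes)
    start = 0
    for cls in planted_path_classes():
        frac = spec.path_fractions.get(cls, 0.0)
        k = int(round(frac * spec.n_genes))
        classes[order[start : start + k]] = cls
        start += k

    non_ref = spec.conditions[1:]
    delta = np.zeros((spec.n_genes, len(spec.conditions)))
    for cls in planted_path_classes():
        mask = classes == cls
        if not mask.any():
            continue
        deltas = spec.class_deltas(cls)
        for j, cond in enumerate(non_ref, start=1):
            delta[mask, j] = deltas[cond]

    lo, hi = spec.baseline_mean_log2_range
    baseline = rng.uniform(lo, hi, size=spec.n_genes)

    sample_names, sample_cond_idx, replicates = [], [], []
    for j, cond in enumerate(spec.conditions):
        for r in range(1, spec.n_replicates + 1):
            sample_names.append(f"{cond}_r{r}")
            sample_cond_idx.append(j)
            replicates.append(r)

    flo, fhi = spec.library_size_factor_range
    depth = 2.0 ** rng.uniform(np.log2(flo), np.log2(fhi), size=len(sample_names))

    mu = 2.0 ** (baseline[:, None] + delta[:, sample_cond_idx]) * depth[None, :]
    # NB(n, p) with n = 1/alpha, p = n / (n + mu) gives var = mu + alpha mu^2.
    nb_n = 1.0 / spec.dispersion
    counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))

    counts_df = pd.DataFrame(counts, index=genes, columns=sample_names)
    counts_df.index.name = "gene"
    meta = pd.DataFrame(
        {
            "condition": [spec.conditions[j] for j in sample_cond_idx],
            "replicate": replicates,
        },
        index=pd.Index(sample_names, name="sample"),
    )
    dataset = CountDataset(counts=counts_df, sample_meta=meta)

    sets, term_truth = _simulate_gene_sets(spec, genes, classes, rng)

    gene_truth = pd.DataFrame({"gene": genes, "path_class": classes})
    for j, cond in enumerate(non_ref, start=1):
        gene_truth[f"lfc_{cond}"] = delta[:, j]
    truth = SyntheticTruth(gene_truth=gene_truth, term_truth=term_truth, spec=spec)
    return dataset, sets, truth


def _simulate_gene_sets(
    spec: SimulationSpec,
    genes: list[str],
    classes: np.ndarray,
    rng: np.random.Generator,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    gene_arr = np.asarray(genes, dtype=object)
    planted_by_term = {
        term: (cls, frac) for cls, (term, frac) in spec.planted_enrichment.items()
    }
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    rows = []
    lo, hi = spec.term_size_range
    for i in range(spec.n_terms):
        term_id = f"T{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        size = min(size, spec.n_genes)
        if term_id in planted_by_term:
            cls, frac = planted_by_term[term_id]
            members_in = gene_arr[classes == cls]
            n_in = min(int(round(frac * size)), len(members_in))
            chosen_in = rng.choice(members_in, size=n_in, replace=False)
            pool = gene_arr[~np.isin(gene_arr, chosen_in)]
            chosen_out = rng.choice(pool, size=size - n_in, replace=False)
            members = frozenset(chosen_in) | frozenset(chosen_out)
            rows.append(
                {
                    "term": term_id,
                    "planted": True,
                    "target_class": cls,
                    "planted_fraction": n_in / size,
                }
            )
        else:
            members = frozenset(rng.choice(gene_arr, size=size, replace=False))
            rows.append(
                {
                    "term": term_id,
                    "planted": False,
                    "target_class": "",
                    "planted_fraction": 0.0,
                }
            )
        terms[term_id] = (f"synthetic term {i + 1}", members)
    return GeneSetCollection(terms=terms), pd.DataFrame(rows)


def write_truth(truth: SyntheticTruth, gene_path, term_path) -> None:
    """Write the truth manifest as two TSV tables."""
    truth.gene_truth.to_csv(gene_path, sep="\t", index=False)
    truth.term_truth.to_csv(term_path, sep="\t", index=False)
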