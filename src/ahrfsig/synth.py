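"""Synthetic twin-cohort generator with known ground truth.

Emulates the structure of two public pediatric AHRF whole-blood microarray
cohorts (a 26-control / 70-case ARDS cohort and a 65-control / 96-case sepsis
cohort): log2-scale intensities, multi-probe redundancy, batch structure and a
planted set of class-informative genes partially shared between cohorts.  The
generator is the ground-truth oracle for every downstream stage, so its output
is fully deterministic for a fixed seed.

Expression model (log2 scale): per gene g a baseline b_g ~ N(7, 1.5); the gene
signal of sample s is b_g + s_g * effect_size * [informative and case]
+ batch_offset(batch(s)) + N(0, noise_sd), with the effect sign s_g drawn ±1
per informative gene.  Each probe of a gene observes the gene signal plus
independent probe noise N(0, 0.25 * noise_sd).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CASE, CONTROL, ExpressionMatrix

_BASELINE_MEAN = 7.0
_BASELINE_SD = 1.5
_PROBE_NOISE_FRAC = 0.25

#: per-gene probe-count distribution: 70% one probe, 25% two, 5% three
DEFAULT_PROBE_MULTIPLICITY: tuple[tuple[int, float], ...] = (
    (1, 0.70), (2, 0.25), (3, 0.05),
)


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``effect_size`` is the mean log2-expression shift of informative genes in
    cases; ``noise_sd`` the within-class SD on the log2 scale.  Defaults give a
    clearly detectable but not trivial signal (effect 2x the noise SD) at
    desk-scale gene counts.
    """

    n_cases: int
    n_controls: int
    n_genes: int = 5000
    n_informative: int = 50
    effect_size: float = 1.0
    noise_sd: float = 0.5
    probe_multiplicity: tuple[tuple[int, float], ...] = DEFAULT_PROBE_MULTIPLICITY
    n_batches: int = 1
    batch_shift_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample counts must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_informative > self.n_genes:
            raise ValueError(
                f"n_informative ({self.n_informative}) > n_genes ({self.n_genes})")
        if self.n_informative < 0 or self.n_batches < 1:
            raise ValueError("n_informative >= 0 and n_batches >= 1 required")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        probs = [p for _, p in self.probe_multiplicity]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("probe multiplicity probabilities must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth emitted with each cohort: what was planted and where."""

    informative_genes: list[str]
    effect_signs: dict[str, int]            # gene id -> +1 / -1
    class_labels: dict[str, str]            # sample id -> case / control
    batch_labels: dict[str, str]            # sample id -> batch id
    effect_size: float = 0.0
    noise_sd: float = 0.0

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
        # trailing newline keeps the file POSIX-friendly and diff-stable
        with open(path, "a") as fh:
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _draw_probe_counts(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    counts = np.array([c for c, _ in spec.probe_multiplicity])
    probs = np.array([p for _, p in spec.probe_multiplicity])
    return rng.choice(counts, size=spec.n_genes, p=probs)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(spec: CohortSpec,
                    informative_genes: list[str] | None = None,
                    gene_ids: list[str] | None = None,
                    sample_prefix: str = "S") -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate one probe-level cohort and its ground truth.

    ``informative_genes`` / ``gene_ids`` let paired generation impose a shared
    gene universe and a chosen informative set; by default both are drawn from
    the spec's own seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    genes = list(gene_ids) if gene_ids is not None else _gene_ids(spec.n_genes)
    if len(genes) != spec.n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    if informative_genes is None:
        informative = sorted(rng.choice(genes, size=spec.n_informative,
                                        replace=False).tolist())
    else:
        if len(informative_genes) != spec.n_informative:
            raise ValueError("informative_genes length must equal n_informative")
        unknown = set(informative_genes) - set(genes)
        if unknown:
            raise ValueError(f"informative genes outside universe: {sorted(unknown)[:5]}")
        informative = sorted(informative_genes)

    n = spec.n_cases + spec.n_controls
    samples = [f"{sample_prefix}{i:03d}" for i in range(1, n + 1)]
    # interleave-ish assignment then fixed: first controls, then cases
    class_arr = np.array([CONTROL] * spec.n_controls + [CASE] * spec.n_cases)
    batch_arr = np.array([f"batch{i % spec.n_batches}" for i in range(n)])

    signs = {g: int(s) for g, s in
             zip(informative, rng.choice([-1, 1], size=len(informative)))}

    baseline = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=spec.n_genes)
    effect = np.zeros(spec.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in informative:
        effect[gene_pos[g]] = signs[g] * spec.effect_size

    case_mask = (class_arr == CASE).astype(float)
    batch_offsets = rng.normal(0.0, spec.batch_shift_sd, size=spec.n_batches)
    sample_offset = np.array([batch_offsets[int(b[5:])] for b in batch_arr])

    # gene signal: (n_genes, n_samples)
    signal = (baseline[:, None]
              + effect[:, None] * case_mask[None, :]
              + sample_offset[None, :]
              + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n)))

    probe_counts = _draw_probe_counts(rng, spec)
    probe_rows = []
    probe_ids = []
    probe_gene = []
    for i, g in enumerate(genes):
        for k in range(probe_counts[i]):
            probe_ids.append(f"{g}_p{k + 1}")
            probe_gene.append(g)
            probe_rows.append(i)
    probe_rows = np.asarray(probe_rows)
    probe_noise = rng.normal(0.0, _PROBE_NOISE_FRAC * spec.noise_sd,
                             size=(len(probe_ids), n))
    values = pd.DataFrame(signal[probe_rows, :] + probe_noise,
                          index=pd.Index(probe_ids, name="probe_id"),
                          columns=samples)

    classes = pd.Series(class_arr, index=values.columns)
    batches = pd.Series(batch_arr, index=values.columns)
    m = ExpressionMatrix(values=values, classes=classes, batches=batches,
                         level="probe",
                         meta={"annotation": dict(zip(probe_ids, probe_gene))})
    truth = SyntheticTruth(
        informative_genes=informative,
        effect_signs=signs,
        class_labels=dict(zip(samples, class_arr.tolist())),
        batch_labels=dict(zip(samples, batch_arr.tolist())),
        effect_size=spec.effect_size,
        noise_sd=spec.noise_sd,
    )
    return m, truth


def generate_paired_cohorts(
    spec_a: CohortSpec, spec_b: CohortSpec, shared_informative: int,
) -> tuple[tuple[ExpressionMatrix, SyntheticTruth], tuple[ExpressionMatrix, SyntheticTruth]]:
    """Generate two cohorts over one gene universe with a shared planted core.

    Exactly ``shared_informative`` gene IDs are informative in both cohorts;
    the remaining informative genes of each cohort are disjoint between the
    two, so the intersection of the truth sets has the requested size.
    """
    spec_a.validate()
    spec_b.validate()
    if spec_a.n_genes != spec_b.n_genes:
        raise ValueError("paired cohorts need identical gene universes")
    if shared_informative > min(spec_a.n_informative, spec_b.n_informative):
        raise ValueError("shared_informative exceeds a cohort's n_informative")
    if shared_informative < 0:
        raise ValueError("shared_informative must be >= 0")

    genes = _gene_ids(spec_a.n_genes)
    extra_a = spec_a.n_informative - shared_informative
    extra_b = spec_b.n_informative - shared_informative
    if shared_informative + extra_a + extra_b > spec_a.n_genes:
        raise ValueError("gene universe too small for the requested truth sets")

    rng = np.random.default_rng(np.random.SeedSequence([spec_a.seed, spec_b.seed, 7]))
    picked = rng.choice(genes, size=shared_informative + extra_a + extra_b,
                        replace=False).tolist()
    shared = picked[:shared_informative]
    inf_a = sorted(shared + picked[shared_informative:shared_informative + extra_a])
    inf_b = sorted(shared + picked[shared_informative + extra_a:])

    pair_a = generate_cohort(spec_a, informative_genes=inf_a, gene_ids=genes,
                             sample_prefix="A")
    pair_b = generate_cohort(spec_b, informative_genes=inf_b, gene_ids=genes,
                             sample_prefix="B")
    return pair_a, pair_b


# --------------------------------------------------------------------- sets
def generate_gene_sets(universe: list[str], n_sets: int,
                       size_range: tuple[int, int],
                       planted_set: list[str], seed: int = 0,
                       planted_name: str = "PLANTED"):
    """Gene-set collection with one set equal to ``planted_set``.

    Remaining ``n_sets - 1`` sets are drawn uniformly from the universe with
    sizes uniform in ``size_range``.  Returns a
    :class:`~ahrfsig.enrich.GeneSetCollection`.
    """
    from .enrich import GeneSetCollection

    if not planted_set:
        raise ValueError("planted_set must be non-empty")
    unknown = set(planted_set) - set(universe)
    if unknown:
        raise ValueError(f"planted genes outside universe: {sorted(unknown)[:5]}")
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError("size_range must satisfy 1 <= lo <= hi <= |universe|")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")

    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {planted_name: sorted(planted_set)}
    descriptions = {planted_name: "planted informative gene set"}
    for i in range(1, n_sets):
        name = f"RANDOM{i:03d}"
        size = int(rng.integers(lo, hi + 1))
        sets[name] = sorted(rng.choice(universe, size=size, replace=False).tolist())
        descriptions[name] = "random background set"
    return GeneSetCollection(sets=sets, descriptions=descriptions,
                             universe=set(universe))


# ------------------------------------------------------------------ network
def generate_network(universe: list[str], planted_hubs: list[str],
                     hub_degree: int = 10, background_degree_mean: float = 1.0,
                     seed: int = 0):
    """Sparse interaction graph with planted high-degree hubs.

    Background edges follow an Erdős–Rényi model with the requested mean
    degree; each planted hub then gets additional random partners until its
    degree reaches ``hub_degree``.  Simple graph (no self-loops or duplicate
    edges); SIF-writable via :func:`ahrfsig.network.write_sif`.
    """
    import networkx as nx

    n = len(universe)
    if hub_degree < 1:
        raise ValueError("hub_degree must be >= 1")
    if hub_degree > n - 1:
        raise ValueError(f"hub_degree ({hub_degree}) > |universe| - 1 ({n - 1})")
    unknown = set(planted_hubs) - set(universe)
    if unknown:
        raise ValueError(f"planted hubs outside universe: {sorted(unknown)[:5]}")
    if background_degree_mean < 0:
        raise ValueError("background_degree_mean must be >= 0")

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(universe)
    p = min(1.0, background_degree_mean / max(n - 1, 1))
    nodes = list(universe)
    if p > 0:
        # vectorized upper-triangle coin flips
        for i in range(n - 1):
            draws = rng.random(n - 1 - i) < p
            for j in np.nonzero(draws)[0]:
                g.add_edge(nodes[i], nodes[i + 1 + j])
    for hub in planted_hubs:
        others = [v for v in nodes if v != hub and not g.has_edge(hub, v)]
        need = hub_degree - g.degree(hub)
        if need > 0:
            partners = rng.choice(others, size=need, replace=False)
            g.add_edges_from((hub, v) for v in partners)
    return g


# --------------------------------------------------------------------- files
def write_annotation_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    """Probe→gene annotation table as emitted inside the cohort metadata."""
    annot = m.meta.get("annotation")
    if annot is None:
        raise ValueError("matrix carries no probe annotation")
    df = pd.DataFrame({"probe_id": list(annot.keys()),
                       "gene_id": list(annot.values())})
    df.to_csv(path, sep="\t", index=False)


def write_cohort(m: ExpressionMatrix, truth: SyntheticTruth, out_dir: str | Path,
                 prefix: str = "cohort") -> dict[str, Path]:
    """Write expression, labels, annotation and truth files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / f"{prefix}_expression.tsv",
        "labels": out / f"{prefix}_labels.tsv",
        "annotation": out / f"{prefix}_annotation.tsv",
        "truth": out / f"{prefix}_truth.json",
    }
    m.write(paths["expression"], paths["labels"])
    write_annotation_tsv(m, paths["annotation"])
    truth.write(paths["truth"])
    return paths
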