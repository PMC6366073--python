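"""Synthetic-data generators with planted truth.

Every analysis stage in this package can be exercised without external
downloads: the generators here emit gene trees with planted donor groups,
tool-evidence tables with configured joint category frequencies,
replicate detection/intensity tables with configured state patterns, and
toy genome contigs with planted gene models — each alongside a truth
table recording what was planted.

Two modes exist. In *exact* mode (the default for the calibrated,
bookkeeping-style configurations shipped under ``egmosaic/configs``) the
configured category counts are met exactly, not in expectation, so the
downstream set logic reproduces the configured totals deterministically.
*Sampling* choices (which protein gets which category, taxon draws,
replicate noise) remain random but fully seeded: a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ancestry import TaxonGroupMap
from .genome import Contig, ContigSet, GeneModel, write_gff3
from .expression import DET_COLS, VAL_COLS

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: donor/acceptor dinucleotides planted per splice class (mRNA sense)
SPLICE_BOUNDARIES = {
    "conventional": ("GT", "AG"),
    "intermediate": ("GT", "AC"),
    "nonconventional": ("CA", "TG"),
}

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def load_config(name_or_path: str | Path) -> dict:
    """Load a YAML generator config: a bundled name (e.g. ``gene_ancestry``)
    or a path to a file."""
    p = Path(name_or_path)
    if p.exists():
        return yaml.safe_load(p.read_text())
    res = importlib.resources.files("egmosaic") / "configs" / f"{name_or_path}.yaml"
    return yaml.safe_load(res.read_text())


# ---------------------------------------------------------------------------
# homolog / alignment funnel fixtures
# ---------------------------------------------------------------------------

def gen_homolog_table(config: dict, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BLAST-style hit table: ``n_retained`` proteins with >= min_hits
    qualifying hits, ``n_excluded`` with fewer.

    Returns (table, truth) where truth marks each protein retained or not
    under the configured E-value/hit-count rule.
    """
    rng = np.random.default_rng(seed)
    n_ret = int(config["n_retained"])
    n_exc = int(config["n_excluded"])
    e_max = float(config.get("e_max", 1e-2))
    min_hits = int(config.get("min_hits", 3))

    pids, hits_n, truth_flags = [], [], []
    order = rng.permutation(n_ret + n_exc)
    for i in order:
        retained = i < n_ret
        pid = f"P{i:06d}"
        if retained:
            n = min_hits + int(rng.integers(0, 3))
            n_good = n
        else:
            n = int(rng.integers(0, min_hits))     # 0..min_hits-1 good hits
            n_good = n
            n += int(rng.integers(0, 2))           # maybe one failing hit
        pids.append(pid)
        hits_n.append((n, n_good))
        truth_flags.append((pid, retained))

    rows = []
    for pid, (n, n_good) in zip(pids, hits_n):
        for h in range(n):
            good = h < n_good
            ev = 10 ** rng.uniform(-30, np.log10(e_max) - 1e-9) if good \
                else 10 ** rng.uniform(np.log10(e_max), 2)
            rows.append((pid, f"{pid}_hit{h}", ev))
    table = pd.DataFrame(rows, columns=["protein_id", "hit_id", "evalue"])
    truth = pd.DataFrame(truth_flags, columns=["protein_id", "retained"])
    return table, truth


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

def build_taxonomy(config: dict) -> TaxonGroupMap:
    """Taxonomy implied by a tree config: ``taxa_per_group`` ids per group,
    named ``<GROUPPREFIX><k>``."""
    n_taxa = int(config.get("taxa_per_group", 4))
    groups = {
        g: {f"{_group_prefix(g)}{k}" for k in range(n_taxa)}
        for g in config["groups"]
    }
    return TaxonGroupMap(groups, config["focal_taxon"])


def _group_prefix(group: str) -> str:
    return "".join(ch for ch in group if ch.isalnum()).upper()[:6]


def gen_gene_trees(config: dict, seed: int
                   ) -> tuple[list[tuple[str, str]], TaxonGroupMap, pd.DataFrame]:
    """Planted-donor gene trees.

    For each planted tree the focal taxon forms a clan with two members of
    the planted donor group at the configured support; leaves from other
    groups fill the background. Optional noise trees carry sub-threshold
    support or a mixed-group sister clan and are labelled unclassifiable
    in the truth table.

    Returns (list of (name, newick), taxonomy, truth).
    """
    rng = np.random.default_rng(seed)
    taxmap = build_taxonomy(config)
    focal = config["focal_taxon"]
    support = int(config.get("support_planted", 95))
    bg_support = config.get("support_background", [20, 74])
    groups = list(config["groups"])

    jobs: list[tuple[str | None, str]] = []   # (planted group or None, kind)
    for g, n in config.get("bins", {}).items():
        if g not in taxmap.groups:
            raise ValueError(f"planted group {g!r} not in taxonomy")
        jobs += [(g, "planted")] * int(n)
    noise = config.get("noise", {})
    jobs += [(None, "low_support")] * int(noise.get("low_support", 0))
    jobs += [(None, "mixed_clan")] * int(noise.get("mixed_clan", 0))
    rng.shuffle(jobs)

    trees, truth_rows = [], []
    for i, (g, kind) in enumerate(jobs):
        name = f"tree{i:05d}"
        if kind == "planted":
            nwk = _planted_newick(g, taxmap, focal, support, bg_support,
                                  groups, rng)
            truth_rows.append((name, g, support, kind))
        elif kind == "low_support":
            gg = groups[int(rng.integers(len(groups)))]
            low = int(config.get("support_noise", 60))
            nwk = _planted_newick(gg, taxmap, focal, low, bg_support,
                                  groups, rng)
            truth_rows.append((name, None, low, kind))
        else:  # mixed_clan: sister clade drawn from two groups
            g1, g2 = rng.choice(len(groups), size=2, replace=False)
            nwk = _mixed_newick(groups[g1], groups[g2], taxmap, focal,
                                support, bg_support, groups, rng)
            truth_rows.append((name, None, support, kind))
        trees.append((name, nwk))

    truth = pd.DataFrame(truth_rows,
                         columns=["tree", "planted_group", "support", "kind"])
    return trees, taxmap, truth


def _pick(taxmap: TaxonGroupMap, group: str, n: int, rng) -> list[str]:
    taxa = sorted(taxmap.groups[group])
    idx = rng.choice(len(taxa), size=n, replace=False)
    return [taxa[i] for i in idx]


def _background(taxmap, exclude: set[str], groups, rng, n=4) -> list[str]:
    """Background leaves spanning at least two groups, so no clan formed
    with the focal leaf outside the planted one is taxonomically
    homogeneous."""
    others = [g for g in groups if g not in exclude]
    if len(others) < 2:
        raise ValueError("need at least two non-planted groups for background")
    idx = list(rng.choice(len(others), size=2, replace=False))
    idx += [int(rng.integers(len(others))) for _ in range(n - 2)]
    leaves = []
    for k, gi in enumerate(idx):
        t = _pick(taxmap, others[gi], 1, rng)[0]
        leaves.append(f"{t}_b{k}")
    return leaves

def _bg_sup(bg_support, rng) -> int:
    return int(rng.integers(bg_support[0], bg_support[1] + 1))


def _planted_newick(group, taxmap, focal, support, bg_support, groups, rng
                    ) -> str:
    d1, d2 = _pick(taxmap, group, 2, rng)
    b = _background(taxmap, {group}, groups, rng)
    s1, s2 = _bg_sup(bg_support, rng), _bg_sup(bg_support, rng)
    return (f"(({focal}_q,({d1}_s1,{d2}_s2){support}){support},"
            f"({b[0]},{b[1]}){s1},({b[2]},{b[3]}){s2});")


def _mixed_newick(g1, g2, taxmap, focal, support, bg_support, groups, rng
                  ) -> str:
    d1 = _pick(taxmap, g1, 1, rng)[0]
    d2 = _pick(taxmap, g2, 1, rng)[0]
    b = _background(taxmap, {g1, g2}, groups, rng)
    s1, s2 = _bg_sup(bg_support, rng), _bg_sup(bg_support, rng)
    return (f"(({focal}_q,({d1}_s1,{d2}_s2){support}){support},"
            f"({b[0]},{b[1]}){s1},({b[2]},{b[3]}){s2});")


def write_trees(trees: list[tuple[str, str]], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "trees.nwk"
    with open(path, "w") as fh:
        for _, nwk in trees:
            fh.write(nwk + "\n")
    return path


# ---------------------------------------------------------------------------
# tool-score tables
# ---------------------------------------------------------------------------

def gen_toolscore_table(config: dict, seed: int
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein tool-evidence table with exact category frequencies.

    The mitochondrial block assigns each protein at most one of
    targetp / ortholog / blast2go / manual plus optional decoy patterns
    (MTERF-flagged annotation, ortholog with non-mitochondrial function,
    score exactly at the threshold). The plastid block independently
    assigns joint signal/transit-peptide call patterns plus enrichment
    flags. Counts are met exactly; which protein gets which label is
    seeded-random.
    """
    rng = np.random.default_rng(seed)
    n = int(config["n_proteins"])
    mito = {k: int(v) for k, v in config.get("mito", {}).items()}
    plastid = {k: int(v) for k, v in config.get("plastid", {}).items()}
    if sum(mito.values()) > n or sum(plastid.values()) > n:
        raise ValueError("category counts exceed proteome size")

    pids = [f"P{i:06d}" for i in range(n)]
    df = pd.DataFrame(index=pd.Index(pids, name="protein_id"))
    df["sequence_length"] = rng.integers(100, 1000, size=n)
    df["targetp_mito_score"] = np.round(rng.uniform(0.0, 0.85, size=n), 4)
    for col in ("ref_mito_ortholog", "ortholog_non_mito_function",
                "blast2go_mito", "mterf_family", "manual_mito",
                "signalp_positive", "predisi_positive", "chlorop_positive",
                "at_chloro_ortholog", "manual_plastid"):
        df[col] = False
    df["signalp_cleavage"] = pd.array([pd.NA] * n, dtype="Int64")
    df["predisi_cleavage"] = pd.array([pd.NA] * n, dtype="Int64")

    mito_label = np.array(_assign_exact(n, mito, rng))
    pl_label = np.array(_assign_exact(n, plastid, rng))

    score = df["targetp_mito_score"].to_numpy().copy()
    m = mito_label == "targetp"
    score[m] = np.round(rng.uniform(0.901, 1.0, size=int(m.sum())), 4)
    score[mito_label == "boundary_score"] = 0.9
    df["targetp_mito_score"] = score
    df["ref_mito_ortholog"] = np.isin(mito_label, ["ortholog", "non_mito_ortholog"])
    df["ortholog_non_mito_function"] = mito_label == "non_mito_ortholog"
    df["blast2go_mito"] = np.isin(mito_label, ["blast2go", "mterf"])
    df["mterf_family"] = mito_label == "mterf"
    df["manual_mito"] = mito_label == "manual"

    sp = np.isin(pl_label, ["signalp_chlorop", "signalp_only",
                            "both_chlorop", "both_no_chlorop"])
    pdi = np.isin(pl_label, ["predisi_chlorop", "predisi_only",
                             "both_chlorop", "both_no_chlorop"])
    cp = np.isin(pl_label, ["signalp_chlorop", "predisi_chlorop",
                            "both_chlorop"])
    atc = pl_label == "atchloro_new"
    man = pl_label == "manual_new"
    df["signalp_positive"] = sp
    df["predisi_positive"] = pdi
    df["chlorop_positive"] = cp
    df["at_chloro_ortholog"] = atc
    df["manual_plastid"] = man
    lens = df["sequence_length"].to_numpy()
    cleave = rng.integers(10, 41, size=n)
    df.loc[sp, "signalp_cleavage"] = cleave[sp]
    df.loc[pdi, "predisi_cleavage"] = np.minimum(cleave[pdi] + 2, lens[pdi] - 1)

    truth = pd.DataFrame({
        "protein_id": pids,
        "mito_category": mito_label,
        "plastid_category": pl_label,
    })
    return df, truth


def _assign_exact(n: int, counts: dict[str, int], rng) -> list[str]:
    """Exact-count label assignment over n items; unlabeled items get
    'none'. Which item gets which label is a seeded permutation."""
    labels = ["none"] * n
    perm = rng.permutation(n)
    pos = 0
    for lab, k in counts.items():
        for j in perm[pos:pos + k]:
            labels[j] = lab
        pos += k
    return labels


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

#: detection masks per pattern name: (light flags, dark flags); partial
#: patterns may list several admissible masks, chosen per feature.
_PATTERNS: dict[str, list[tuple[tuple[int, ...], tuple[int, ...]]]] = {
    "full_full": [((1, 1, 1), (1, 1, 1))],
    "full_light_partial_dark": [((1, 1, 1), (1, 0, 0)), ((1, 1, 1), (1, 1, 0))],
    "full_dark_partial_light": [((1, 0, 0), (1, 1, 1)), ((1, 1, 0), (1, 1, 1))],
    "light_only": [((1, 1, 1), (0, 0, 0))],
    "dark_only": [((0, 0, 0), (1, 1, 1))],
    "partial_partial": [((1, 1, 0), (1, 1, 0)), ((1, 0, 1), (0, 1, 1))],
    "sparse": [((1, 0, 0), (0, 1, 0)), ((0, 0, 0), (1, 0, 0)),
               ((0, 0, 0), (0, 0, 0))],
}

RETAINED_PATTERNS = {"full_full", "full_light_partial_dark",
                     "full_dark_partial_light", "light_only", "dark_only"}
SINGLE_STATE_PATTERNS = {"light_only", "dark_only"}


def gen_expression_tables(config: dict, seed: int) -> dict:
    """Protein-group and transcript replicate tables with exact detection
    patterns and a planted concordance structure.

    Per-gene true log10 light/dark effects are drawn independently for
    protein and RNA except for a plastid-encoded subset that shares one
    effect; replicate intensities are the base intensity shifted by half
    the effect per condition with log-normal noise. Pattern counts are
    exact. Returns a dict with keys ``protein``, ``transcript`` (wide
    replicate tables), ``id_map`` (transcript -> protein group),
    ``plastid_encoded`` (protein-group ids) and ``truth``.
    """
    rng = np.random.default_rng(seed)
    eff = config.get("effects", {})
    effect_sd = float(eff.get("effect_sd", 0.5))
    noise_sd = float(eff.get("noise_sd", 0.05))
    shared = eff.get("shared", "plastid")   # plastid | all | none

    prot_cfg, rna_cfg = config["protein"], config["transcript"]
    n_prot, n_rna = int(prot_cfg["n_features"]), int(rna_cfg["n_features"])
    n_pl = int(config.get("n_plastid_encoded", 0))

    prot_ids = [f"PG{i:06d}" for i in range(n_prot)]
    rna_ids = [f"TR{i:06d}" for i in range(n_rna)]
    n_paired = min(n_prot, n_rna)
    id_map = {rna_ids[i]: prot_ids[i] for i in range(n_paired)}
    plastid = set(prot_ids[:n_pl])

    prot_eff = rng.normal(0, effect_sd, size=n_prot)
    rna_eff = rng.normal(0, effect_sd, size=n_rna)
    if shared == "all":
        rna_eff[:n_paired] = prot_eff[:n_paired]
    elif shared == "plastid":
        rna_eff[:min(n_pl, n_paired)] = prot_eff[:min(n_pl, n_paired)]

    prot_tab, prot_pat = _replicate_table(
        prot_ids, prot_cfg["patterns"], prot_eff, noise_sd, rng, base_log=7.0)
    rna_tab, rna_pat = _replicate_table(
        rna_ids, rna_cfg["patterns"], rna_eff, noise_sd, rng, base_log=2.5)

    truth = pd.DataFrame({
        "protein_id": prot_ids,
        "pattern": prot_pat,
        "true_protein_effect": prot_eff,
        "true_rna_effect": [rna_eff[i] if i < n_rna else np.nan
                            for i in range(n_prot)],
        "plastid_encoded": [p in plastid for p in prot_ids],
    })
    return {"protein": prot_tab, "transcript": rna_tab, "id_map": id_map,
            "plastid_encoded": plastid, "truth": truth,
            "rna_patterns": pd.Series(rna_pat, index=rna_ids)}


def _replicate_table(ids, patterns: dict, effects, noise_sd, rng,
                     base_log: float) -> tuple[pd.DataFrame, list[str]]:
    n = len(ids)
    counts = {k: int(v) for k, v in patterns.items()}
    if sum(counts.values()) != n:
        raise ValueError(f"pattern counts sum to {sum(counts.values())}, "
                         f"expected {n}")
    labels = _assign_exact(n, counts, rng)

    base = 10 ** rng.normal(base_log, 0.5, size=n)
    det = np.zeros((n, 6), dtype=bool)
    val = np.full((n, 6), np.nan)
    for i, lab in enumerate(labels):
        masks = _PATTERNS[lab]
        mask_l, mask_d = masks[int(rng.integers(len(masks)))]
        flags = np.array(mask_l + mask_d, dtype=bool)
        det[i] = flags
        mean_l = base[i] * 10 ** (effects[i] / 2)
        mean_d = base[i] * 10 ** (-effects[i] / 2)
        means = np.array([mean_l] * 3 + [mean_d] * 3)
        noise = 10 ** rng.normal(0, noise_sd, size=6)
        vals = means * noise
        val[i, flags] = vals[flags]

    cols = DET_COLS["light"] + DET_COLS["dark"]
    tab = pd.DataFrame(det, index=pd.Index(ids, name="id"), columns=cols)
    for j, c in enumerate(VAL_COLS["light"] + VAL_COLS["dark"]):
        tab[c] = val[:, j]
    return tab, labels


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------

def gen_toy_genome(config: dict, seed: int
                   ) -> tuple[ContigSet, list[GeneModel], pd.DataFrame]:
    """Toy contigs with planted gene models.

    In exact mode (the default) the configured contig counts, intron
    count, total intron/exon lengths and splice-class mix are met exactly;
    which contig hosts which model, the strand, and the spacer sequence
    are seeded-random. Sequence is materialised only for gene-bearing
    contigs; the remaining contigs carry lengths alone, which suffices for
    every statistic except boundary dinucleotides (none are needed there).
    """
    rng = np.random.default_rng(seed)
    n_contigs = int(config["n_contigs"])
    total_bases = int(config["total_contig_bases"])
    n_gene_contigs = int(config["contigs_with_cds"])
    n_cds = int(config["n_cds"])
    n_introns = int(config["n_introns"])
    tot_intron = int(config["total_intron_length"])
    tot_exon = int(config["total_exon_length"])
    splice_mix = {k: int(v) for k, v in config["splice_counts"].items()}
    if sum(splice_mix.values()) != n_introns:
        raise ValueError("splice-class counts must sum to the intron count")
    gene_len = int(config.get("gene_contig_length", 20_000))
    n_small = int(config.get("n_small_contigs", 0))
    small_len = int(config.get("small_contig_length", 5_000))

    intron_lengths = _exact_partition(tot_intron, n_introns)
    n_exons = n_introns + n_cds
    exon_lengths = _exact_partition(tot_exon, n_exons)

    classes = [c for c, k in splice_mix.items() for _ in range(k)]
    rng.shuffle(classes)

    introns_per_model = _spread(n_introns, n_cds)
    models_per_contig = _spread(n_cds, n_gene_contigs)

    # lay models onto gene-bearing contigs
    gene_contigs: list[Contig] = []
    models: list[GeneModel] = []
    truth_rows = []
    ei = ii = mi = 0
    for ci in range(n_gene_contigs):
        cid = f"contig{ci:05d}"
        seq = rng.choice(_BASES, size=gene_len)
        pos = int(rng.integers(50, 150))
        for _ in range(models_per_contig[ci]):
            tid = f"transcript{mi:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            k_introns = introns_per_model[mi]
            exons = []
            start = pos
            for x in range(k_introns + 1):
                e_len = exon_lengths[ei]; ei += 1
                exons.append((pos, pos + e_len))
                pos += e_len
                if x < k_introns:
                    il = intron_lengths[ii]
                    cls = classes[ii]
                    _plant_boundary(seq, pos, pos + il, strand, cls)
                    truth_rows.append((tid, cid, strand, il, cls))
                    ii += 1
                    pos += il
            models.append(GeneModel(tid, cid, strand, exons))
            mi += 1
            pos += int(rng.integers(100, 300))
        if pos > gene_len:
            raise ValueError("gene models exceed contig length; increase "
                             "gene_contig_length")
        gene_contigs.append(Contig(cid, gene_len, "".join(seq)))

    # remaining large contigs: lengths only, exact total
    n_rest = n_contigs - n_gene_contigs
    rest_total = total_bases - n_gene_contigs * gene_len
    contigs = list(gene_contigs)
    if n_rest:
        rest_lengths = _exact_partition(rest_total, n_rest)
        if min(rest_lengths) <= 10_000:
            raise ValueError("non-gene contig lengths fall below 10 kbp; "
                             "adjust totals")
        contigs += [Contig(f"contig{n_gene_contigs + j:05d}", rest_lengths[j])
                    for j in range(n_rest)]
    contigs += [Contig(f"small{j:04d}", small_len) for j in range(n_small)]

    truth = pd.DataFrame(truth_rows, columns=["transcript_id", "contig_id",
                                              "strand", "intron_length",
                                              "splice_class"])
    return ContigSet(contigs), models, truth


def _plant_boundary(seq: np.ndarray, start: int, end: int, strand: str,
                    cls: str) -> None:
    donor, acceptor = SPLICE_BOUNDARIES[cls]
    if strand == "+":
        seq[start:start + 2] = list(donor)
        seq[end - 2:end] = list(acceptor)
    else:
        seq[end - 2:end] = list(_revcomp(donor))
        seq[start:start + 2] = list(_revcomp(acceptor))


def _exact_partition(total: int, n: int) -> list[int]:
    """n positive integers summing exactly to total, as equal as possible."""
    if n <= 0 or total < n:
        raise ValueError("cannot partition")
    base, rem = divmod(total, n)
    return [base + 1] * rem + [base] * (n - rem)


def _spread(total: int, n_bins: int) -> list[int]:
    base, rem = divmod(total, n_bins)
    return [base + 1] * rem + [base] * (n_bins - rem)


def write_genome(contigs: ContigSet, models: list[GeneModel],
                 out_dir: str | Path) -> dict[str, Path]:
    """Write gene-bearing contigs to FASTA, all contig lengths to TSV and
    models to GFF3."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "contigs.fasta"
    with open(fasta, "w") as fh:
        for c in contigs:
            if c.sequence is not None:
                fh.write(f">{c.id}\n")
                for i in range(0, len(c.sequence), 80):
                    fh.write(c.sequence[i:i + 80] + "\n")
    lengths = out / "contig_lengths.tsv"
    with open(lengths, "w") as fh:
        fh.write("contig_id\tlength\n")
        for c in contigs:
            fh.write(f"{c.id}\t{c.length}\n")
    gff = out / "models.gff3"
    write_gff3(models, gff)
    return {"fasta": fasta, "lengths": lengths, "gff3": gff}


def contigs_from_lengths_tsv(path: str | Path,
                             fasta: str | Path | None = None) -> ContigSet:
    """ContigSet from a lengths TSV, merging sequences from an optional
    FASTA of the subset of contigs that have sequence."""
    seqs: dict[str, str] = {}
    if fasta is not None:
        from Bio import SeqIO
        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta), "fasta")}
    df = pd.read_csv(path, sep="\t")
    return ContigSet([
        Contig(str(r.contig_id), int(r.length), seqs.get(str(r.contig_id)))
        for r in df.itertuples()
    ])
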