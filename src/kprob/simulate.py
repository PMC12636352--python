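"""Synthetic pan-genome / pan-transcriptome fixtures with known ground truth.

Each pangene starts from a random ancestral promoter that is mutated
independently per accession: iid substitutions, short geometric indels, and
structural-variant (SV) insertions of 50-900 bp. A configurable number of
planted motif k-mers carry true expression effects; a motif is planted either
inside an SV insertion (presence/absence of the motif coincides with the SV —
the scenario where reference-alignment methods fail) or written directly into
the ancestral context of carrier alleles at a random offset. Expression is
generated exactly as y_i = mu_g(i) + sum_j count_ij * beta_j + eps_i with
eps ~ N(0, sigma^2), counts obeying the same stride-1/forward-strand
enumeration rules as the k-mer modules.

The mutation model is deliberately simple (no selection, no phylogeny): the
fixtures exercise the inference, not evolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._encode import kmer_codes
from .pan_io import (ExpressionTable, GenomicInterval, PromoterRecord,
                     PromoterSet, write_bed, write_promoter_fasta)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


@dataclass
class PlantedMotif:
    motif: str
    beta: float
    mode: str                      # "sv" or "snp"
    pangenes: list[str]
    carriers: dict = field(default_factory=dict)   # gene_id -> planted copies
    variants: list[str] = field(default_factory=list)  # binding words incl. canonical

    def __post_init__(self):
        if not self.variants:
            self.variants = [self.motif]


@dataclass
class SimTruth:
    planted: list[PlantedMotif]
    baselines: dict                # pangene_id -> mu_g
    noise_sd: float | None
    sv_events: list                # (gene_id, insert_len, carries_motif)
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "baselines": self.baselines,
            "sv_events": self.sv_events,
            "planted": [vars(m) for m in self.planted],
        }, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls([PlantedMotif(**m) for m in d["planted"]],
                   d["baselines"], d["noise_sd"],
                   [tuple(e) for e in d["sv_events"]], d["seed"])


def _random_motifs(rng, n: int, length: int) -> list[str]:
    """Random planted k-mers kept >= 3 mismatches apart (distinct clusters)."""
    out: list[np.ndarray] = []
    while len(out) < n:
        cand = rng.integers(0, 4, length)
        if all((cand != m).sum() >= 3 for m in out):
            out.append(cand)
    return [_codes_to_seq(m.astype(np.uint8)) for m in out]


def simulate_pangenome(n_pangenes: int = 300, n_accessions: int = 26,
                       promoter_len: int = 2000,
                       snp_rate: float = 0.02, indel_rate: float = 0.002,
                       sv_insert_prob: float = 0.05,
                       n_planted: int = 5, motif_len: int = 11,
                       pangenes_per_motif: int | None = None,
                       carrier_prob: float = 0.5,
                       effect_size: float = 1.0,
                       baseline_sd: float = 1.0,
                       motif_mismatch_prob: float = 0.0,
                       noise_sd: float | None = None,
                       seed: int = 0) -> tuple[PromoterSet, SimTruth]:
    """Allelic promoter series with planted motif effects.

    Defaults emulate the study conditions the method targets: ~26 accessions
    per pangene, 2 kb windows, percent-scale substitution divergence and
    occasional SV insertions. Planted motifs alternate between "sv"
    (embedded in an SV insertion of carriers) and "snp" (written into the
    allelic context at a random offset) modes, with alternating-sign effects
    of magnitude ``effect_size`` (log2 units per occurrence).

    ``motif_mismatch_prob`` emulates the degeneracy of real TF binding
    words: with that probability a carrier pangene receives (and is affected
    by) a one-substitution variant of the canonical motif instead of the
    exact word; the variant set is recorded in the truth object and all
    variants carry the motif's effect.
    """
    for rate in (snp_rate, indel_rate, sv_insert_prob):
        if not 0 <= rate < 1:
            raise ValueError("rates must be in [0, 1)")
    if motif_len > promoter_len:
        raise ValueError("planted motif longer than the promoter")
    rng = np.random.default_rng(seed)
    pangene_ids = [f"pan{i:04d}" for i in range(n_pangenes)]
    accession_ids = [f"acc{a:02d}" for a in range(n_accessions)]
    if pangenes_per_motif is None:
        pangenes_per_motif = max(6, n_pangenes // 15)

    planted: list[PlantedMotif] = []
    motif_of_pangene: dict[str, list[PlantedMotif]] = {}
    for m, motif in enumerate(_random_motifs(rng, n_planted, motif_len)):
        beta = effect_size if m % 2 == 0 else -effect_size
        mode = "sv" if m % 2 == 0 else "snp"
        chosen = [pangene_ids[i] for i in
                  rng.choice(n_pangenes, size=min(pangenes_per_motif, n_pangenes),
                             replace=False)]
        pm = PlantedMotif(motif, float(beta), mode, chosen)
        planted.append(pm)
        for pg in chosen:
            motif_of_pangene.setdefault(pg, []).append(pm)

    baselines = {pg: float(rng.normal(2.0, baseline_sd)) for pg in pangene_ids}
    sv_events: list[tuple] = []
    sv_max = min(900, max(60, promoter_len // 2))
    records = []
    for pg in pangene_ids:
        ancestral = rng.integers(0, 4, promoter_len).astype(np.uint8)
        pms = motif_of_pangene.get(pg, [])
        carrier_flags = {}
        pangene_word = {}
        for pm in pms:
            flags = rng.random(n_accessions) < carrier_prob
            if flags.all() or not flags.any():
                flags[rng.integers(n_accessions)] = not flags[0]
            carrier_flags[pm.motif] = flags
            word = pm.motif
            if rng.random() < motif_mismatch_prob:
                w = np.frombuffer(word.encode(), dtype=np.uint8).copy()
                pos = int(rng.integers(len(word)))
                cur = b"ACGT".index(bytes([w[pos]]))
                w[pos] = b"ACGT"[(cur + int(rng.integers(1, 4))) % 4]
                word = w.tobytes().decode()
                if word not in pm.variants:
                    pm.variants.append(word)
            pangene_word[pm.motif] = word
        for a, acc in enumerate(accession_ids):
            gene_id = f"{pg}_{acc}"
            seq = ancestral.copy()
            # substitutions
            hit = rng.random(seq.size) < snp_rate
            shift = rng.integers(1, 4, int(hit.sum())).astype(np.uint8)
            seq[hit] = (seq[hit] + shift) % 4
            # short indels (geometric lengths, capped)
            n_ind = rng.binomial(seq.size, indel_rate)
            for _ in range(n_ind):
                pos = int(rng.integers(0, seq.size))
                length = min(int(rng.geometric(0.5)), 10)
                if rng.random() < 0.5:
                    ins = rng.integers(0, 4, length).astype(np.uint8)
                    seq = np.concatenate([seq[:pos], ins, seq[pos:]])
                else:
                    seq = np.concatenate([seq[:pos], seq[pos + length:]])
            # background SV insertion
            if rng.random() < sv_insert_prob:
                sv_len = int(rng.integers(50, sv_max + 1))
                ins = rng.integers(0, 4, sv_len).astype(np.uint8)
                pos = int(rng.integers(seq.size // 2, seq.size + 1))
                seq = np.concatenate([seq[:pos], ins, seq[pos:]])
                sv_events.append((gene_id, sv_len, False))
            # planted motifs
            for pm in pms:
                if not carrier_flags[pm.motif][a]:
                    continue
                motif_codes = np.array(
                    [b"ACGT".index(ch.encode())
                     for ch in pangene_word[pm.motif]],
                    dtype=np.uint8)
                if pm.mode == "sv":
                    sv_len = int(rng.integers(max(50, motif_len + 10), sv_max + 1))
                    ins = rng.integers(0, 4, sv_len).astype(np.uint8)
                    off = int(rng.integers(0, sv_len - motif_len + 1))
                    ins[off:off + motif_len] = motif_codes
                    pos = int(rng.integers(seq.size // 2, seq.size + 1))
                    seq = np.concatenate([seq[:pos], ins, seq[pos:]])
                    sv_events.append((gene_id, sv_len, True))
                else:
                    pos = int(rng.integers(seq.size // 2,
                                           seq.size - motif_len + 1))
                    seq[pos:pos + motif_len] = motif_codes
                pm.carriers[gene_id] = pm.carriers.get(gene_id, 0) + 1
            # keep the TSS-proximal window
            if seq.size > promoter_len:
                seq = seq[-promoter_len:]
            seq_str = _codes_to_seq(seq)
            interval = GenomicInterval(f"chr_{gene_id}", 1000,
                                       1000 + len(seq_str), "+")
            records.append(PromoterRecord(pg, acc, gene_id, seq_str, interval))
    truth = SimTruth(planted, baselines, noise_sd, sv_events, seed)
    return PromoterSet(records), truth


def simulate_expression(promoters: PromoterSet, truth: SimTruth,
                        seed: int = 0,
                        signal_fraction: float = 0.6,
                        default_noise_sd: float = 0.5) -> ExpressionTable:
    """Expression from the additive generative model.

    Motif counts are recomputed from the final sequences with the same
    stride-1 forward-strand rule as the k-mer modules, so chance occurrences
    contribute too. When ``truth.noise_sd`` is unset it is calibrated so the
    planted signal explains ``signal_fraction`` of the non-baseline variance
    (or ``default_noise_sd`` for motif-free fixtures), and written back into
    the truth object.
    """
    genes = promoters.gene_ids
    signal = np.zeros(len(genes))
    counts = np.zeros((len(genes), len(truth.planted)))
    for j, pm in enumerate(truth.planted):
        codes = _variant_codes(pm)
        for i, rec in enumerate(promoters):
            c = kmer_codes(rec.sequence, len(pm.motif))
            counts[i, j] = int(np.isin(c, codes).sum())
        signal += counts[:, j] * pm.beta
    if truth.noise_sd is None:
        var_sig = float(np.var(signal))
        if var_sig > 0:
            truth.noise_sd = float(
                np.sqrt(var_sig * (1 - signal_fraction) / signal_fraction))
        else:
            truth.noise_sd = default_noise_sd
    rng = np.random.default_rng(seed)
    mu = np.array([truth.baselines[rec.pangene_id] for rec in promoters])
    y = mu + signal + rng.normal(0.0, truth.noise_sd, len(genes))
    return ExpressionTable(dict(zip(genes, y.astype(float))))


def _variant_codes(pm: PlantedMotif) -> np.ndarray:
    return np.array([kmer_codes(v, len(pm.motif))[0] for v in pm.variants])


def planted_count_matrix(promoters: PromoterSet,
                         truth: SimTruth) -> np.ndarray:
    """True per-gene occurrence counts of each planted motif's binding words
    (genes sorted by gene_id, matching count-matrix row order)."""
    ordered = list(promoters.sorted_by_gene())
    counts = np.zeros((len(ordered), len(truth.planted)))
    for j, pm in enumerate(truth.planted):
        codes = _variant_codes(pm)
        for i, rec in enumerate(ordered):
            counts[i, j] = int(np.isin(
                kmer_codes(rec.sequence, len(pm.motif)), codes).sum())
    return counts


def attribute_selections(matrix, selected_columns, promoters: PromoterSet,
                         truth: SimTruth,
                         min_corr: float = 0.8) -> tuple[dict, list[int]]:
    """Attribute selected clusters to planted motifs by count correlation.

    K-mer windows overlapping a planted site by k-1 bases form their own
    cluster that is (near-)collinear with the motif's literal cluster, and
    posterior inclusion mass can land on either; a selection is therefore
    credited to a motif when its count column correlates with the motif's
    true carrier counts at |r| >= ``min_corr``. Returns
    (motif index -> list of attributed columns, unattributed columns).
    """
    true_counts = planted_count_matrix(promoters, truth)
    attributed: dict[int, list[int]] = {j: [] for j in range(len(truth.planted))}
    false_cols: list[int] = []
    for col in np.asarray(selected_columns, dtype=int):
        x = np.asarray(matrix.X[:, col].todense()).ravel()
        hit = None
        for j in range(true_counts.shape[1]):
            t = true_counts[:, j]
            if np.std(t) == 0 or np.std(x) == 0:
                continue
            if abs(np.corrcoef(x, t)[0, 1]) >= min_corr:
                hit = j
                break
        if hit is None:
            false_cols.append(int(col))
        else:
            attributed[hit].append(int(col))
    return attributed, false_cols


def write_fixture(outdir: str | Path, promoters: PromoterSet,
                  expression: ExpressionTable, truth: SimTruth,
                  peaks: bool = True, peak_pad: int = 10) -> dict[str, Path]:
    """Emit FASTA / TSV / JSON (+ optional planted-site peak BED) files.

    The expression TSV holds log2-scale values (load with transform='none').
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "promoters": outdir / "promoters.fa",
        "expression": outdir / "expression.tsv",
        "membership": outdir / "membership.tsv",
        "truth": outdir / "truth.json",
    }
    write_promoter_fasta(promoters, paths["promoters"])
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\texpression\n")
        for rec in promoters:
            fh.write(f"{rec.gene_id}\t{expression[rec.gene_id]:.8g}\n")
    with open(paths["membership"], "w") as fh:
        fh.write("pangene_id\tgene_id\taccession_id\n")
        for rec in promoters:
            fh.write(f"{rec.pangene_id}\t{rec.gene_id}\t{rec.accession_id}\n")
    paths["truth"].write_text(truth.to_json())
    if peaks:
        intervals, names = [], []
        for pm in truth.planted:
            codes = _variant_codes(pm)
            for gene_id in sorted(pm.carriers):
                rec = promoters[gene_id]
                if rec.interval is None:
                    continue
                c = kmer_codes(rec.sequence, len(pm.motif))
                for off in np.flatnonzero(np.isin(c, codes)):
                    start = max(0, rec.interval.start + int(off) - peak_pad)
                    end = rec.interval.start + int(off) + len(pm.motif) + peak_pad
                    intervals.append(GenomicInterval(rec.interval.contig,
                                                     start, end, "+"))
                    names.append(f"peak_{pm.motif}")
        paths["peaks"] = outdir / "peaks.bed"
        write_bed(intervals, paths["peaks"], names=names)
    return paths
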