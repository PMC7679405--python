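"""Synthetic annotated genomes, small-RNA reads, and replicate count matrices.

Every quantity the downstream analysis measures is *planted* here with a
recoverable truth label, so the whole pipeline can be verified without any
external data: category mixtures (transposon / satellite / genic / ncRNA
blacklist), transposon sense:antisense strand bias, the 23-29 nt piRNA
length distribution, ping-pong read pairs (opposite-strand reads whose 5'
ends overlap by exactly 10 nt), and negative-binomial replicate counts with
a planted differential-expression direction mixture.

Genome sequences are rejection-sampled so that every k-mer of length
``uniqueness_k`` occurs exactly once genome-wide, counting both strands.
This makes exact mapping of any read at least ``uniqueness_k`` long
unambiguous and lets classification logic be tested in isolation from
multimapping noise.  Two deliberate departures from real genomes follow
from that choice and are documented in the methods note: satellite loci are
unique placeholder sequence rather than literal tandem repeats, and
transposon copies of a family share only their annotation, not their
sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    BLACKLIST_TYPES,
    GENIC_TYPES,
    SATELLITE_TYPE,
    TRANSPOSON_TYPE,
    AnnotatedGenome,
    CollapsedRead,
    FeatureInterval,
    revcomp,
)

_BASES = "ACGT"

CATEGORIES = ("transposon", "satellite", "genic", "blacklist")
GENIC_FEATURES = ("exon", "intron", "utr5", "utr3")
_FEATURE_TO_GFF = {"exon": "CDS", "intron": "intron",
                   "utr5": "five_prime_UTR", "utr3": "three_prime_UTR"}


def _check_simplex(name: str, probs: dict, keys: tuple) -> None:
    if set(probs) != set(keys):
        raise ValueError(f"{name} must have keys {keys}, got {sorted(probs)}")
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions sum to {total}, expected 1")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{name} has negative proportions")


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Layout parameters of a forged genome.

    Gene models are ``utr5 | exon (intron exon)* | utr3`` on a random
    strand; transposon families carry a class attribute (LTR or LINE) and
    copies in both orientations; satellite and ncRNA-blacklist loci are
    standalone intervals.  All lengths are nucleotides.
    """

    n_genes: int = 30
    exons_per_gene: int = 3
    utr5_len: int = 200
    utr3_len: int = 250
    exon_len: int = 300
    intron_len: int = 200
    n_te_families: int = 8
    te_class_mix: dict = field(default_factory=lambda: {"LTR": 0.5, "LINE": 0.5})
    te_len_range: tuple[int, int] = (800, 2000)
    te_copies_per_family: int = 4
    satellite_unit: int = 260
    satellite_copies: int = 6
    n_blacklist_loci: int = 3          # per class in {tRNA, rRNA, snRNA, snoRNA}
    uniqueness_k: int = 18
    n_contigs: int = 2
    gap_range: tuple[int, int] = (100, 300)
    seed: int = 0

    def validate(self) -> None:
        k = self.uniqueness_k
        lengths = [self.utr5_len, self.utr3_len, self.exon_len, self.intron_len,
                   self.te_len_range[0], self.satellite_unit]
        if self.n_genes < 0 or self.exons_per_gene < 1:
            raise ValueError("n_genes must be >= 0 and exons_per_gene >= 1")
        if any(L < k for L in lengths):
            raise ValueError(f"all feature lengths must be >= uniqueness_k={k}")
        if self.te_len_range[0] > self.te_len_range[1]:
            raise ValueError("empty te_len_range")
        _check_simplex("te_class_mix", self.te_class_mix, ("LTR", "LINE"))


_BLACKLIST_LENGTHS = {"tRNA": 80, "rRNA": 150, "snRNA": 120, "snoRNA": 100}


@dataclass
class ReadProfile:
    """Planted composition of a simulated small-RNA population.

    ``te_sense_fraction`` is the probability that a transposon read matches
    its element's strand; ``pingpong_pair_fraction`` is the probability that
    a transposon read additionally spawns an opposite-strand partner whose
    5' end overlaps its own 5' end by exactly 10 nt (partners consume read
    slots, see :meth:`expected_category_shares`).
    """

    category_mix: dict = field(default_factory=lambda: dict(
        transposon=0.25, satellite=0.05, genic=0.65, blacklist=0.05))
    genic_feature_mix: dict = field(default_factory=lambda: dict(
        exon=0.25, intron=0.25, utr5=0.25, utr3=0.25))
    te_sense_fraction: float = 0.5
    genic_sense_fraction: float = 0.5
    length_dist: dict = field(default_factory=lambda: {
        23: 0.08, 24: 0.16, 25: 0.22, 26: 0.22, 27: 0.16, 28: 0.10, 29: 0.06})
    pingpong_pair_fraction: float = 0.0
    #: per-read abundance: round(lognormal(meanlog, sdlog)), floored at 1,
    #: split over samples as independent Poisson draws
    abundance_meanlog: float = math.log(24.0)
    abundance_sdlog: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        _check_simplex("category_mix", self.category_mix, CATEGORIES)
        _check_simplex("genic_feature_mix", self.genic_feature_mix, GENIC_FEATURES)
        for name in ("te_sense_fraction", "genic_sense_fraction",
                     "pingpong_pair_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.length_dist.values()) - 1.0) > 1e-9:
            raise ValueError("length_dist must sum to 1")
        if not all(18 <= L <= 35 for L in self.length_dist):
            raise ValueError("length support must lie within [18, 35]")

    def expected_category_shares(self) -> dict[str, float]:
        """Analytic category shares among emitted reads.

        Ping-pong partners are always transposon reads, so a nonzero
        ``pingpong_pair_fraction`` f inflates the transposon share relative
        to ``category_mix``: each transposon draw emits 1 + f reads in
        expectation.  These are the planted values recovery tests compare
        against.
        """
        w = dict(self.category_mix)
        w["transposon"] *= 1.0 + self.pingpong_pair_fraction
        total = sum(w.values())
        return {c: v / total for c, v in w.items()}

    def expected_retained_shares(self) -> dict[str, float]:
        """Category shares after blacklist removal (renormalized)."""
        shares = self.expected_category_shares()
        keep = {c: v for c, v in shares.items() if c != "blacklist"}
        total = sum(keep.values())
        return {c: v / total for c, v in keep.items()}


@dataclass
class DEPlan:
    """Planted two-group negative-binomial count experiment.

    ``dispersion`` is the NB overdispersion phi with Var = mu + phi mu^2;
    DE features have group-B mean ``baseline_mean * 2**(+-log2fc_magnitude)``
    with the minus sign for a ``down_fraction_among_de`` share.
    """

    n_features: int = 2000
    de_fraction: float = 0.3
    down_fraction_among_de: float = 0.5
    log2fc_magnitude: float = 3.0
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    replicates_per_group: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.de_fraction <= 1.0
                and 0.0 <= self.down_fraction_among_de <= 1.0):
            raise ValueError("fractions must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.replicates_per_group < 2:
            raise ValueError("need >= 2 replicates per group")
        if self.baseline_mean <= 0 or self.log2fc_magnitude <= 0:
            raise ValueError("baseline_mean and log2fc_magnitude must be > 0")


@dataclass
class TruthLabel:
    """Hidden ground truth for one simulated read."""

    category: str                       # transposon | satellite | genic | blacklist
    feature: str = "none"               # exon | intron | utr5 | utr3 | none
    sense: str = "none"                 # sense | antisense | none
    source_feature_id: str = ""
    te_class: str = "none"
    de_direction: str = "null"          # up | down | null
    contig: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    is_pingpong_partner: bool = False

    def __post_init__(self):
        if (self.feature != "none") != (self.category == "genic"):
            raise ValueError("feature must be set iff category is genic")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset_profile(name: str, seed: int = 0) -> ReadProfile:
    """Named read-population presets.

    ``brain``: mostly genic piRNAs (87.8%), 10% transposon with a sense
    bias, 0.2% satellite, no ping-pong pairing.  ``ovary``: 90% transposon
    with an antisense bias, 2.3% satellite, 30% ping-pong pairing, genic
    reads mostly intronic.  ``brain_tud``: the brain profile with the
    transposon sense bias eliminated (sense fraction 0.5).

    The category and genic-feature percentages are the printed wild-type
    compositions these presets emulate; the brain intron/5'UTR split and
    the numeric sense fractions are not printed anywhere and are this
    module's declared artifact defaults, not external claims.
    """
    if name == "brain":
        return ReadProfile(
            category_mix=dict(transposon=0.10, satellite=0.002,
                              genic=0.878, blacklist=0.02),
            genic_feature_mix=dict(exon=0.62, intron=0.11, utr5=0.05, utr3=0.22),
            te_sense_fraction=0.70,
            pingpong_pair_fraction=0.0,
            seed=seed,
        )
    if name == "brain_tud":
        prof = preset_profile("brain", seed=seed)
        return replace(prof, te_sense_fraction=0.5)
    if name == "ovary":
        return ReadProfile(
            category_mix=dict(transposon=0.90, satellite=0.023,
                              genic=0.057, blacklist=0.02),
            genic_feature_mix=dict(exon=0.12, intron=0.66, utr5=0.15, utr3=0.07),
            te_sense_fraction=0.30,
            pingpong_pair_fraction=0.30,
            seed=seed,
        )
    raise ValueError(f"unknown profile preset {name!r}")


def preset_deplan(name: str, seed: int = 0) -> DEPlan:
    """DE presets: brain plants 85% of DE features down, ovary 39%."""
    if name == "brain":
        return DEPlan(down_fraction_among_de=0.85, seed=seed)
    if name == "ovary":
        return DEPlan(down_fraction_among_de=0.39, seed=seed)
    raise ValueError(f"unknown DE preset {name!r}")


# ---------------------------------------------------------------------------
# Genome forging
# ---------------------------------------------------------------------------

class _UniqueSeqBuilder:
    """Grows contig sequences whose canonical k-mers are globally unique.

    Bases are drawn one at a time; a base whose new k-mer window (or its
    reverse complement) was already seen anywhere in the genome is redrawn.
    Fails after ``max_rejects`` consecutive dead ends (spec too dense for
    the k-mer space).
    """

    def __init__(self, k: int, rng: np.random.Generator, max_rejects: int = 200):
        self.k = k
        self.rng = rng
        self.max_rejects = max_rejects
        self.kmers: set[str] = set()
        self.chars: list[str] = []
        self.tail = ""

    def append(self, n: int) -> None:
        k = self.k
        for _ in range(n):
            for attempt in range(self.max_rejects):
                base = _BASES[self.rng.integers(4)]
                if len(self.tail) < k - 1:
                    break
                kmer = self.tail + base
                canon = min(kmer, revcomp(kmer))
                if canon not in self.kmers:
                    self.kmers.add(canon)
                    break
            else:
                raise RuntimeError(
                    f"k-mer uniqueness (k={k}) unsatisfiable after "
                    f"{self.max_rejects} rejections; genome too dense"
                )
            self.chars.append(base)
            self.tail = (self.tail + base)[-(k - 1):]

    def finish_contig(self) -> str:
        seq = "".join(self.chars)
        self.chars = []
        self.tail = ""          # k-mers do not span contig boundaries
        return seq

    @property
    def pos(self) -> int:
        return len(self.chars)


def build_genome(spec: GenomeSpec) -> AnnotatedGenome:
    """Forge an annotated genome per ``spec``.

    Features are placed at non-overlapping positions separated by random
    background gaps, round-robin across ``n_contigs`` contigs.  Gene parts
    abut without gaps, ordered along the genome according to the gene's
    strand.  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    builder = _UniqueSeqBuilder(spec.uniqueness_k, rng)

    # plan features (category-level) first, then interleave across contigs
    plans: list[tuple] = []
    for g in range(spec.n_genes):
        plans.append(("gene", f"gene{g + 1:04d}"))
    # allocate family classes by largest remainder so both classes are
    # represented whenever their mix weight warrants it
    n_ltr = int(round(spec.n_te_families * spec.te_class_mix["LTR"]))
    fam_classes = ["LTR"] * n_ltr + ["LINE"] * (spec.n_te_families - n_ltr)
    for f in range(spec.n_te_families):
        te_class = fam_classes[f]
        fam = f"TEfam{f + 1:02d}"
        for c in range(spec.te_copies_per_family):
            strand = "+" if c % 2 == 0 else "-"    # both orientations per family
            length = int(rng.integers(spec.te_len_range[0], spec.te_len_range[1] + 1))
            plans.append(("te", fam, te_class, strand, length, c + 1))
    for s in range(spec.satellite_copies):
        plans.append(("satellite", f"sat{s + 1:02d}"))
    for btype in BLACKLIST_TYPES:
        for b in range(spec.n_blacklist_loci):
            plans.append(("blacklist", btype, f"{btype}{b + 1:02d}"))
    order = rng.permutation(len(plans))

    n_contigs = max(1, spec.n_contigs)
    per_contig: list[list[tuple]] = [[] for _ in range(n_contigs)]
    for i, idx in enumerate(order):
        per_contig[i % n_contigs].append(plans[idx])

    contigs: dict[str, str] = {}
    features: list[FeatureInterval] = []
    lo, hi = spec.gap_range
    for ci in range(n_contigs):
        contig = f"chrS{ci + 1}"
        for plan in per_contig[ci]:
            builder.append(int(rng.integers(lo, hi + 1)))
            kind = plan[0]
            if kind == "gene":
                gene_id = plan[1]
                strand = "+" if rng.integers(2) == 0 else "-"
                parts = [("five_prime_UTR", spec.utr5_len)]
                for e in range(spec.exons_per_gene):
                    if e > 0:
                        parts.append(("intron", spec.intron_len))
                    parts.append(("CDS", spec.exon_len))
                parts.append(("three_prime_UTR", spec.utr3_len))
                if strand == "-":
                    parts = parts[::-1]      # 5'UTR sits at the right end
                for j, (ftype, length) in enumerate(parts):
                    start = builder.pos
                    builder.append(length)
                    features.append(FeatureInterval(
                        contig, start, builder.pos, strand, ftype,
                        {"ID": f"{gene_id}.p{j + 1}", "gene_id": gene_id}))
            elif kind == "te":
                _, fam, te_class, strand, length, copy = plan
                start = builder.pos
                builder.append(length)
                features.append(FeatureInterval(
                    contig, start, builder.pos, strand, TRANSPOSON_TYPE,
                    {"ID": f"{fam}.c{copy}", "family": fam, "class": te_class}))
            elif kind == "satellite":
                sat_id = plan[1]
                start = builder.pos
                builder.append(spec.satellite_unit)
                features.append(FeatureInterval(
                    contig, start, builder.pos, "+", SATELLITE_TYPE,
                    {"ID": sat_id, "family": sat_id}))
            else:
                _, btype, bid = plan
                strand = "+" if rng.integers(2) == 0 else "-"
                start = builder.pos
                builder.append(_BLACKLIST_LENGTHS[btype])
                features.append(FeatureInterval(
                    contig, start, builder.pos, strand, btype, {"ID": bid}))
        builder.append(int(rng.integers(lo, hi + 1)))
        contigs[contig] = builder.finish_contig()

    features.sort(key=lambda f: (f.contig, f.start))
    genome = AnnotatedGenome(contigs=contigs, features=features)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _feature_pools(genome: AnnotatedGenome) -> dict:
    pools: dict = {"transposon": [], "satellite": [], "blacklist": [],
                   "genic": {f: [] for f in GENIC_FEATURES}}
    for f in genome.features:
        if f.ftype == TRANSPOSON_TYPE:
            pools["transposon"].append(f)
        elif f.ftype == SATELLITE_TYPE:
            pools["satellite"].append(f)
        elif f.ftype in BLACKLIST_TYPES:
            pools["blacklist"].append(f)
        elif f.ftype in GENIC_TYPES:
            pools["genic"][GENIC_TYPES[f.ftype]].append(f)
    return pools


def simulate_reads(
    genome: AnnotatedGenome,
    profile: ReadProfile,
    n_reads: int,
    n_samples: int = 4,
    deplan: DEPlan | None = None,
) -> list[tuple[CollapsedRead, TruthLabel]]:
    """Simulate ``n_reads`` small-RNA reads with hidden truth labels.

    Each read is an exact substring (or reverse complement) of one source
    feature, with category, genic feature class, length, and strand drawn
    from ``profile``.  For ``pingpong_pair_fraction`` of transposon reads an
    opposite-strand partner with an exact 10-nt 5'-5' overlap is emitted
    (consuming one of the ``n_reads`` slots).

    Per-read abundance is lognormal, split over ``n_samples`` samples as
    independent Poisson draws (floored so every read keeps total >= 1).
    When ``deplan`` is given, samples are halved into groups A then B and a
    ``de_fraction`` of reads get their group-B rate scaled by
    ``2**(+-log2fc_magnitude)``; the drawn direction lands in the truth
    label.

    Raises ``ValueError`` if a drawn read length exceeds its source feature
    length, or if a category with positive mix weight has no features.
    """
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    pools = _feature_pools(genome)
    for cat in CATEGORIES:
        if profile.category_mix[cat] <= 0:
            continue
        pool = pools[cat]
        if cat == "genic":
            for feat, p in profile.genic_feature_mix.items():
                if p > 0 and not pool[feat]:
                    raise ValueError(f"no {feat} features for nonzero genic mix")
        elif not pool:
            raise ValueError(f"no {cat} features for nonzero mix weight")

    cats = list(CATEGORIES)
    cat_p = np.array([profile.category_mix[c] for c in cats])
    gf = list(GENIC_FEATURES)
    gf_p = np.array([profile.genic_feature_mix[f] for f in gf])
    lengths = np.array(sorted(profile.length_dist))
    len_p = np.array([profile.length_dist[L] for L in lengths])

    if deplan is not None:
        deplan.validate()
        # replicates_per_group only governs simulate_counts; here the
        # sample split supplies the replicates (half A, half B)
        if n_samples < 4:
            raise ValueError("a DE plant needs >= 2 samples per group")
    n_a = n_samples // 2

    # pre-draw in blocks for speed; refilled lazily
    def draws(n):
        return {
            "cat": rng.choice(len(cats), size=n, p=cat_p),
            "gfeat": rng.choice(len(gf), size=n, p=gf_p),
            "len": lengths[rng.choice(len(lengths), size=n, p=len_p)],
            "u": rng.random(size=(n, 4)),
        }

    merged: dict[str, list] = {}
    emitted = 0
    block = draws(n_reads)
    bi = 0

    def emit(seq: str, label: TruthLabel) -> None:
        nonlocal emitted
        total = max(1, int(round(rng.lognormal(profile.abundance_meanlog,
                                               profile.abundance_sdlog))))
        lam = np.full(n_samples, total / n_samples, dtype=float)
        if deplan is not None and rng.random() < deplan.de_fraction:
            down = rng.random() < deplan.down_fraction_among_de
            label.de_direction = "down" if down else "up"
            scale = 2.0 ** (-deplan.log2fc_magnitude if down
                            else deplan.log2fc_magnitude)
            lam[n_a:] *= scale
        counts = rng.poisson(lam)
        if counts.sum() == 0:
            counts[int(rng.integers(n_samples))] = 1
        if seq in merged:
            merged[seq][0] += counts
        else:
            merged[seq] = [counts, label]
        emitted += 1

    while emitted < n_reads:
        if bi >= len(block["cat"]):
            block = draws(max(64, n_reads - emitted))
            bi = 0
        cat = cats[block["cat"][bi]]
        L = int(block["len"][bi])
        u_feat, u_sense, u_pp, u_pos = block["u"][bi]
        bi += 1

        if cat == "genic":
            feat_class = gf[int(block["gfeat"][bi - 1])]
            pool = pools["genic"][feat_class]
            sense_p = profile.genic_sense_fraction
        else:
            feat_class = "none"
            pool = pools[cat]
            sense_p = profile.te_sense_fraction if cat == "transposon" else 0.5
        feat = pool[int(u_feat * len(pool))]
        if L > feat.length:
            raise ValueError(
                f"read length {L} exceeds source feature {feat.feature_id} "
                f"({feat.length} nt)")
        contig_seq = genome.contigs[feat.contig]
        is_sense = u_sense < sense_p
        strand = feat.strand if is_sense else ("-" if feat.strand == "+" else "+")

        pair = (cat == "transposon"
                and u_pp < profile.pingpong_pair_fraction
                and emitted + 1 < n_reads)
        if pair:
            # place mate so that the opposite-strand partner fits too
            L2 = int(lengths[rng.choice(len(lengths), p=len_p)])
            if strand == "+":
                lo_s = feat.start + max(0, L2 - 10)
                hi_s = feat.end - L
            else:
                # mate 5' at end-1; partner (+) spans [start+L-10, start+L-10+L2)
                lo_s = feat.start
                hi_s = feat.end - L - max(0, L2 - 10)
            if hi_s <= lo_s:
                pair = False
        if not pair:
            start = feat.start + int(u_pos * (feat.length - L + 1))
        else:
            start = lo_s + int(u_pos * (hi_s - lo_s))
        end = start + L
        seq = contig_seq[start:end]
        if strand == "-":
            seq = revcomp(seq)
        label = TruthLabel(
            category=cat, feature=feat_class,
            sense="sense" if is_sense else "antisense",
            source_feature_id=feat.feature_id,
            te_class=feat.attrs.get("class", "none"),
            contig=feat.contig, start=start, end=end, strand=strand,
        )
        emit(seq, label)

        if pair:
            # partner: opposite strand, 5' ends overlap by exactly 10 nt
            fp = start if strand == "+" else end - 1
            if strand == "+":
                p_fp = fp + 9                       # minus-strand partner 5'
                p_start, p_end = p_fp - L2 + 1, p_fp + 1
                p_strand = "-"
            else:
                p_fp = fp - 9                       # plus-strand partner 5'
                p_start, p_end = p_fp, p_fp + L2
                p_strand = "+"
            p_start = max(p_start, feat.start)
            p_end = min(p_end, feat.end)
            pseq = contig_seq[p_start:p_end]
            if p_strand == "-":
                pseq = revcomp(pseq)
            plabel = TruthLabel(
                category="transposon", feature="none",
                sense="antisense" if is_sense else "sense",
                source_feature_id=feat.feature_id,
                te_class=feat.attrs.get("class", "none"),
                contig=feat.contig, start=p_start, end=p_end, strand=p_strand,
                is_pingpong_partner=True,
            )
            emit(pseq, plabel)

    out = []
    for i, (seq, (counts, label)) in enumerate(merged.items(), start=1):
        out.append((CollapsedRead(id=f"sim{i:06d}", sequence=seq,
                                  counts=counts), label))
    return out


def reads_to_fastq_records(
    sim: list[tuple[CollapsedRead, TruthLabel]], sample: int,
):
    """Expand simulated collapsed reads into per-occurrence FASTQ records."""
    for read, _ in sim:
        for c in range(int(read.counts[sample])):
            yield f"{read.id}_s{sample}_{c + 1}", read.sequence


def truth_table(sim: list[tuple[CollapsedRead, TruthLabel]]) -> pd.DataFrame:
    """Truth labels as a tidy table (one row per unique simulated read)."""
    rows = []
    for read, t in sim:
        rows.append(dict(
            read_id=read.id, sequence=read.sequence, total=read.total,
            category=t.category, feature=t.feature, sense=t.sense,
            source_feature_id=t.source_feature_id, te_class=t.te_class,
            de_direction=t.de_direction, contig=t.contig, start=t.start,
            end=t.end, strand=t.strand,
            is_pingpong_partner=t.is_pingpong_partner,
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def simulate_counts(plan: DEPlan) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate an NB count matrix with planted differential expression.

    Returns ``(counts, truth)``: a features x samples integer DataFrame
    with columns ``A1..An, B1..Bn`` and a Series of planted directions in
    ``{"up", "down", "null"}``.  Group-A mean is ``baseline_mean``
    everywhere; DE features scale the group-B mean by
    ``2**(+-log2fc_magnitude)``.
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    n, reps = plan.n_features, plan.replicates_per_group
    is_de = rng.random(n) < plan.de_fraction
    is_down = rng.random(n) < plan.down_fraction_among_de
    direction = np.where(is_de, np.where(is_down, "down", "up"), "null")
    fc = np.where(is_de, 2.0 ** np.where(is_down, -plan.log2fc_magnitude,
                                         plan.log2fc_magnitude), 1.0)
    mu = np.empty((n, 2 * reps))
    mu[:, :reps] = plan.baseline_mean
    mu[:, reps:] = (plan.baseline_mean * fc)[:, None]
    r = 1.0 / plan.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    ids = [f"feat{i + 1:05d}" for i in range(n)]
    cols = [f"A{j + 1}" for j in range(reps)] + [f"B{j + 1}" for j in range(reps)]
    df = pd.DataFrame(counts, index=pd.Index(ids, name="feature"), columns=cols)
    return df, pd.Series(direction, index=df.index, name="direction")


def simulate_gene_de(
    truth: pd.DataFrame,
    concordance: float = 0.8,
    n_background_genes: int = 200,
    lfc_scale: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Fabricate a gene-level DE table concordant with the planted piRNA DE.

    Gene-level differential expression is an *input* to the concordance
    stage (the read-level RNA-seq pipeline is out of scope), so this
    fabricates it jointly with the piRNA plant: each gene targeted by an
    antisense genic piRNA with a planted DE direction is made significantly
    DE in the *opposite* direction with probability ``concordance`` (same
    direction otherwise), emulating the quadrant structure where
    down-regulated antisense piRNAs sit on up-regulated genes.  Untargeted
    background genes receive null q-values.  Columns: ``gene_id, log2fc, q``.
    """
    rng = np.random.default_rng(seed)
    hits = truth[(truth["category"] == "genic")
                 & (truth["sense"] == "antisense")
                 & (truth["de_direction"] != "null")]
    rows, seen = [], set()
    for info in hits.sort_values("read_id").itertuples(index=False):
        gene_id = str(info.source_feature_id).split(".")[0]
        if gene_id in seen:
            continue
        seen.add(gene_id)
        pirna_down = info.de_direction == "down"
        opposite = rng.random() < concordance
        gene_up = pirna_down == opposite
        mag = abs(rng.normal(lfc_scale, 0.4)) + 0.1
        rows.append(dict(gene_id=gene_id, log2fc=mag if gene_up else -mag,
                         q=float(rng.uniform(1e-6, 0.04))))
    for g in range(n_background_genes):
        rows.append(dict(gene_id=f"bg_gene{g + 1:04d}",
                         log2fc=float(rng.normal(0, 0.3)),
                         q=float(rng.uniform(0.2, 1.0))))
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "q"])
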