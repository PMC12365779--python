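"""Summary values reported by the original granulosa-cell GAD/MDD methylome
study, embedded as plain-text constants.

The study's raw sequencing data are not publicly deposited, so its
genome-wide results cannot be recomputed.  What *can* be checked is the
reporting arithmetic: region size from the printed coordinates, stratified
percentages from the printed counts, the hyper/hypo bookkeeping, and the
opposite-direction intersection of the two comparisons' region tables.
These constants are the inputs to those checks; nothing here feeds the
statistical machinery.

``disease`` refers to the untreated-vs-control comparison and
``treatment`` to the treated-vs-untreated comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

# Top-ranked DMRs per comparison, as printed: location, size (bp), state,
# significant CpGs, island/shore/other constituent counts, q, mean and max
# methylation difference, feature, genic annotation.
_DISEASE_DMR_TSV = """\
chr8\t134464025\t134464977\t952\thyper\t3\t3\t0\t0\t9.33e-192\t44.73\t69.83\tZFAT-AS1\tintergenic
chr8\t134465743\t134466734\t991\thypo\t4\t4\t0\t0\t1.40e-79\t-39.04\t-49.26\tZFAT-AS1\tintron
chr10\t75168362\t75168390\t28\thypo\t3\t0\t0\t3\t4.26e-54\t-47.17\t-53.35\tVDAC2\tpromoter
chr17\t250658\t251102\t444\thypo\t3\t0\t3\t0\t6.87e-49\t-29.39\t-31.39\tLINC02091\tintron
chr3\t12787451\t12787816\t365\thyper\t6\t0\t0\t6\t1.34e-44\t33.01\t43.81\tCAND2\tintron
chr12\t47248949\t47249295\t346\thypo\t4\t0\t0\t4\t2.23e-42\t-33.56\t-38.62\tPCED1B-AS1\tintron
chr16\t87875035\t87875071\t36\thypo\t3\t0\t0\t3\t9.44e-41\t-45.59\t-51.09\tSLC7A5\tintergenic
chr8\t54283185\t54283259\t74\thyper\t4\t0\t0\t4\t5.66e-37\t41.68\t42.39\tRNU105C\tpromoter
chr4\t183013908\t183013952\t44\thypo\t4\t0\t0\t4\t2.54e-36\t-27.70\t-33.10\tCIBAR1P2\tpromoter
chr11\t67800245\t67801123\t878\thypo\t4\t0\t0\t4\t4.05e-35\t-35.59\t-39.81\tFAM86C2P\tpromoter & intron
chr2\t236855875\t236856034\t159\thypo\t3\t0\t0\t3\t4.17e-34\t-41.56\t-45.22\tLOC93463\t1-5 kb
chr2\t239938929\t239938957\t28\thyper\t4\t4\t0\t0\t6.01e-33\t34.88\t42.59\tMIR4786\tintron
chr4\t8556471\t8556540\t69\thyper\t4\t0\t0\t4\t1.12e-32\t35.50\t45.97\tGPR78\t1-5 kb
chr16\t88279356\t88280072\t716\thypo\t3\t0\t3\t0\t2.47e-32\t-31.76\t-35.57\tLINC02182\tenhancer
chr6\t151085999\t151086136\t137\thypo\t3\t0\t0\t3\t3.05e-32\t-40.68\t-48.90\tMIR12131\tintergenic
chr21\t43961525\t43961645\t120\thyper\t3\t0\t3\t0\t1.45e-31\t30.08\t33.50\tAGPAT3\t1-5 kb
chr11\t71402909\t71403089\t180\thyper\t4\t0\t0\t4\t4.87e-31\t30.39\t34.62\tACTE1P\tintron
chr3\t172244356\t172244414\t58\thypo\t3\t0\t0\t3\t9.68e-31\t-31.96\t-32.10\tFNDC3B\tintron
chr8\t3021883\t3022166\t283\thypo\t5\t1\t4\t0\t4.00e-30\t-32.96\t-37.78\tLINC03021\tpromoter & 1-5 kb
chr19\t1732992\t1733009\t17\thypo\t4\t0\t4\t0\t6.02e-30\t-47.30\t-49.54\tONECUT3\t1-5 kb
"""

_TREATMENT_DMR_TSV = """\
chr8\t134465815\t134466775\t960\thyper\t5\t5\t0\t0\t4.97e-100\t37.15\t56.99\tZFAT-AS1\tintergenic
chr10\t75168362\t75168390\t28\thyper\t3\t0\t0\t3\t4.96e-68\t53.42\t59.28\tSAMD8\tintron
chr6\t168229488\t168229516\t28\thyper\t3\t3\t0\t0\t7.50e-53\t43.02\t50.65\tLOC105378137\tpromoter
chr20\t63645516\t63645631\t115\thypo\t4\t0\t0\t4\t2.60e-52\t-39.77\t-49.33\tSTMN3\tintron
chr8\t3021883\t3022166\t283\thyper\t6\t2\t4\t0\t2.32e-48\t36.14\t45.95\tCSMD1\tintron
chr16\t88279356\t88280072\t716\thyper\t4\t0\t4\t0\t7.94e-41\t42.97\t47.39\tLINC02182\tintron
chr8\t134464801\t134464986\t185\thyper\t3\t3\t0\t0\t4.28e-40\t40.75\t62.61\tZFAT-AS1\tintergenic
chr7\t36095116\t36095121\t5\thyper\t3\t0\t0\t1\t1.17e-39\t46.27\t48.76\tLOC101928618\tpromoter
chr12\t132733029\t132733635\t606\thyper\t3\t3\t0\t0\t6.85e-38\t26.62\t27.29\tANKLE2\tpromoter
chr5\t146099390\t146100159\t769\thypo\t3\t0\t0\t3\t2.21e-37\t-35.59\t-37.25\tPLAC8L1\tpromoter & intron
chr4\t8556471\t8556540\t69\thypo\t3\t0\t0\t3\t2.24e-34\t-37.50\t-49.61\tGPR78\t1-5 kb
chr10\t13473094\t13473335\t241\thyper\t3\t1\t2\t0\t2.73e-34\t36.47\t41.83\tBEND7\tintron
chr8\t141252974\t141253072\t98\thyper\t3\t3\t0\t0\t9.02e-33\t33.72\t39.31\tLOC105375787\t1-5 kb
chr4\t183013908\t183013952\t44\thyper\t5\t0\t0\t5\t3.12e-32\t27.69\t31.96\tCIBAR1P2\tenhancer
chr19\t1732992\t1733009\t17\thyper\t4\t0\t4\t0\t9.22e-32\t51.25\t54.24\tONECUT3\tintergenic
chr19\t302255\t302349\t94\thypo\t3\t0\t0\t3\t1.15e-31\t-35.87\t-40.76\tPLPP2\t1-5 kb
chr20\t61389938\t61390813\t875\thyper\t5\t1\t4\t0\t1.41e-30\t34.59\t39.39\tCDH4\tintron
chr3\t172244356\t172244414\t58\thyper\t3\t0\t0\t3\t2.17e-29\t31.38\t33.05\tFNDC3B\tintron
chr17\t82318384\t82319375\t991\thypo\t3\t3\t0\t0\t2.79e-29\t-27.93\t-32.06\tCD7\tpromoter & 1-5 kb
chr7\t158959871\t158960025\t154\thyper\t3\t3\t0\t0\t7.53e-29\t30.79\t32.37\tLINC00689\t1-5 kb
"""

# Regions reported in both comparisons: location start, size, state, feature.
_OPPOSING_DISEASE_TSV = """\
chr3\t97018895\t28\thypo\tEPHA6
chr4\t8556471\t69\thyper\tGPR78
chr6\t29680691\t625\thyper\tZFP57
chr16\t87875035\t36\thypo\tSLC7A5
chr17\t78399340\t214\thypo\tPGS1
chr19\t1732992\t17\thypo\tONECUT3
"""

_OPPOSING_TREATMENT_TSV = """\
chr3\t97018895\t28\thyper\tEPHA6
chr4\t8556471\t69\thypo\tGPR78
chr6\t29680691\t625\thypo\tZFP57
chr16\t87875035\t36\thyper\tSLC7A5
chr17\t78399340\t214\thyper\tPGS1
chr19\t1732992\t17\thyper\tONECUT3
"""

# Printed DMS tallies per comparison.
DMS_COUNTS: dict[str, dict[str, int]] = {
    "disease": {"hyper": 1854, "hypo": 1975},
    "treatment": {"hyper": 1741, "hypo": 1949},
}

# Printed CpG-context counts over DMSs and over unique genomic features.
CONTEXT_COUNTS: dict[str, dict[str, int]] = {
    "disease": {"island": 343, "shore": 313, "other": 3173},
    "treatment": {"island": 284, "shore": 295, "other": 3111},
}
FEATURE_CONTEXT_COUNTS: dict[str, dict[str, int]] = {
    "disease": {"island": 212, "shore": 228, "other": 2244},
    "treatment": {"island": 191, "shore": 214, "other": 2170},
}

# Printed coding/noncoding split of features within +-5 kb of a TSS.
BIOTYPE_PERCENTS: dict[str, dict[str, float]] = {
    "disease": {"coding": 68.3, "noncoding": 31.7},
}


@dataclass(frozen=True)
class ReportedDMR:
    """One printed DMR row, with size as printed (for arithmetic checks)."""

    chrom: str
    start: int
    end: int
    printed_size_bp: int
    state: str
    sig_cpgs: int
    n_island: int
    n_shore: int
    n_other: int
    q_value: float
    mean_md: float
    max_md: float
    genomic_feature: str
    genic_annotation: str


def reported_dmrs(comparison: str) -> list[ReportedDMR]:
    """The printed top-ranked DMR rows for 'disease' or 'treatment'."""
    text = {"disease": _DISEASE_DMR_TSV, "treatment": _TREATMENT_DMR_TSV}[comparison]
    rows = []
    for line in text.strip().splitlines():
        f = line.split("\t")
        rows.append(
            ReportedDMR(
                chrom=f[0],
                start=int(f[1]),
                end=int(f[2]),
                printed_size_bp=int(f[3]),
                state=f[4],
                sig_cpgs=int(f[5]),
                n_island=int(f[6]),
                n_shore=int(f[7]),
                n_other=int(f[8]),
                q_value=float(f[9]),
                mean_md=float(f[10]),
                max_md=float(f[11]),
                genomic_feature=f[12],
                genic_annotation=f[13],
            )
        )
    return rows


@dataclass(frozen=True)
class ReportedRegion:
    """A region row from the shared-region table: anchor, size, state, feature."""

    chrom: str
    start: int
    end: int
    state: str
    genomic_feature: str


def reported_shared_regions(comparison: str) -> list[ReportedRegion]:
    """Rows of the common-region table for 'disease' or 'treatment'."""
    text = {
        "disease": _OPPOSING_DISEASE_TSV,
        "treatment": _OPPOSING_TREATMENT_TSV,
    }[comparison]
    rows = []
    for line in text.strip().splitlines():
        chrom, start, size, state, feature = line.split("\t")
        rows.append(
            ReportedRegion(chrom, int(start), int(start) + int(size), state, feature)
        )
    return rows
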