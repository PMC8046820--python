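# 12-SNV LDL-C polygenic score panel.
#
# Weights are per effect allele in mmol/l, all oriented to the LDL-raising
# allele (positive by construction).  The rsIDs, genes and alleles are the
# classic 12-SNV LDL-C score loci; the frequencies and weights shipped here
# are a calibrated stand-in for the validated score's published table: they
# are scaled so that the implied population score distribution places its
# 90th percentile at the clinical cutoff 1.16 (population mean ~0.88,
# SD ~0.217 under Hardy-Weinberg).  Replace with measured values for any
# real-data use; the code treats this panel purely as data.
snv_panel:
  - {id: rs629301,   gene_region: CELSR2/SORT1, chrom: "1",  pos: 109818306, effect_allele: T, other_allele: G, eaf: 0.77, weight: 0.119}
  - {id: rs1367117,  gene_region: APOB,         chrom: "2",  pos: 21263900,  effect_allele: A, other_allele: G, eaf: 0.30, weight: 0.134}
  - {id: rs4299376,  gene_region: ABCG5/ABCG8,  chrom: "2",  pos: 44072576,  effect_allele: G, other_allele: T, eaf: 0.30, weight: 0.103}
  - {id: rs3757354,  gene_region: MYLIP,        chrom: "6",  pos: 16127407,  effect_allele: C, other_allele: T, eaf: 0.77, weight: 0.032}
  - {id: rs1800562,  gene_region: HFE,          chrom: "6",  pos: 26093141,  effect_allele: G, other_allele: A, eaf: 0.94, weight: 0.024}
  - {id: rs1564348,  gene_region: SLC22A1/LPA,  chrom: "6",  pos: 160578860, effect_allele: C, other_allele: T, eaf: 0.17, weight: 0.071}
  - {id: rs11220462, gene_region: ST3GAL4,      chrom: "11", pos: 126243952, effect_allele: A, other_allele: G, eaf: 0.14, weight: 0.087}
  - {id: rs8017377,  gene_region: NYNRIN,       chrom: "14", pos: 24883887,  effect_allele: A, other_allele: G, eaf: 0.47, weight: 0.063}
  - {id: rs6511720,  gene_region: LDLR,         chrom: "19", pos: 11202306,  effect_allele: G, other_allele: T, eaf: 0.89, weight: 0.071}
  - {id: rs2479409,  gene_region: PCSK9,        chrom: "1",  pos: 55504650,  effect_allele: G, other_allele: A, eaf: 0.30, weight: 0.071}
  - {id: rs429358,   gene_region: APOE,         chrom: "19", pos: 45411941,  effect_allele: C, other_allele: T, eaf: 0.15, weight: 0.285}
  - {id: rs7412,     gene_region: APOE,         chrom: "19", pos: 45412079,  effect_allele: C, other_allele: T, eaf: 0.92, weight: 0.055}
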