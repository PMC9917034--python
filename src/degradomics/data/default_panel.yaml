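# Default HLA class I allele panel (27 alleles) used for ligand annotation.
#
# Labels mark alleles reported in the multiple-sclerosis genetics literature as
# risk-associated or protective; "unlabeled" entries are common class I alleles
# padding the panel to its documented size of 27. Edit freely — allele names
# must stay unique.
alleles:
  - {allele: "HLA-A*03:01", label: MS-associated}
  - {allele: "HLA-A*23:01", label: MS-associated}
  - {allele: "HLA-A*24:02", label: MS-associated}
  - {allele: "HLA-A*26:01", label: MS-associated}
  - {allele: "HLA-A*30:01", label: MS-associated}
  - {allele: "HLA-A*30:02", label: MS-associated}
  - {allele: "HLA-A*31:01", label: MS-associated}
  - {allele: "HLA-A*33:01", label: MS-associated}
  - {allele: "HLA-B*07:02", label: MS-associated}
  - {allele: "HLA-B*08:01", label: MS-associated}
  - {allele: "HLA-B*15:01", label: MS-associated}
  - {allele: "HLA-B*51:01", label: MS-associated}
  - {allele: "HLA-A*02:06", label: MS-protective}
  - {allele: "HLA-B*35:01", label: MS-protective}
  - {allele: "HLA-B*44:02", label: MS-protective}
  - {allele: "HLA-B*44:03", label: MS-protective}
  - {allele: "HLA-A*01:01", label: unlabeled}
  - {allele: "HLA-A*02:01", label: unlabeled}
  - {allele: "HLA-A*11:01", label: unlabeled}
  - {allele: "HLA-A*32:01", label: unlabeled}
  - {allele: "HLA-A*68:01", label: unlabeled}
  - {allele: "HLA-B*18:01", label: unlabeled}
  - {allele: "HLA-B*27:05", label: unlabeled}
  - {allele: "HLA-B*40:01", label: unlabeled}
  - {allele: "HLA-C*04:01", label: unlabeled}
  - {allele: "HLA-C*07:01", label: unlabeled}
  - {allele: "HLA-C*07:02", label: unlabeled}
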