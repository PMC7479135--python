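# Known repeat-expansion disease loci screened by trlandscape.
#
# Coordinates are GRCh37 (hs37d5 contig names, no "chr" prefix), 0-based
# half-open, and deliberately small anchor intervals: screening tolerates a
# configurable slop around them because anchored-IRR locus localization is
# broad.  Motifs are given in any orientation and canonicalized on load.
# Repeat-count thresholds are literature-derived configuration values, not
# measurements made by this package; where sources disagree the conservative
# bound is used for flagging and the contested lower bound is recorded in
# pathogenic_min_contested.
diseases:
  - code: ALS
    name: Amyotrophic lateral sclerosis (C9orf72)
    inheritance: AD
    contig: "9"
    start: 27573483
    end: 27573544
    reference_motif: GGGGCC
    disease_motif: GGGGCC
    normal_max_repeats: 23
    pathogenic_min_repeats: 60
    pathogenic_min_contested: 30
    notes: Some sources consider 30 repeats sufficient; 60 is the conservative cutoff.
  - code: FRAXA
    name: Fragile X site A (FMR1)
    inheritance: XD
    contig: X
    start: 146993569
    end: 146993628
    reference_motif: CGG
    disease_motif: CGG
    normal_max_repeats: 44
    pathogenic_min_repeats: 200
    pathogenic_min_contested: 55
    notes: 55-200 repeats is the FXTAS premutation range; >=200 causes Fragile X.
  - code: FRDA
    name: Friedreich ataxia (FXN)
    inheritance: AR
    contig: "9"
    start: 71652202
    end: 71652221
    reference_motif: GAA
    disease_motif: GAA
    normal_max_repeats: 27
    pathogenic_min_repeats: 66
    pathogenic_min_contested: 44
    notes: Typical pathogenic alleles carry 66-1300 repeats; cases down to 44 reported.
  - code: FECD
    name: Fuchs endothelial corneal dystrophy 3 (TCF4)
    inheritance: AD
    contig: "18"
    start: 53253385
    end: 53253460
    reference_motif: CTG
    disease_motif: CTG
    normal_max_repeats: 40
    pathogenic_min_repeats: 50
    notes: Common late-onset condition; expanded alleles reported in ~3% of controls.
  - code: HD
    name: Huntington disease (HTT)
    inheritance: AD
    contig: "4"
    start: 3076603
    end: 3076660
    reference_motif: CAG
    disease_motif: CAG
    normal_max_repeats: 26
    pathogenic_min_repeats: 40
    pathogenic_min_contested: 36
    notes: 36-39 repeats show reduced penetrance; >=40 fully penetrant.
  - code: CANVAS
    name: Cerebellar ataxia with neuropathy and vestibular areflexia (RFC1)
    inheritance: AR
    contig: "4"
    start: 39350044
    end: 39350095
    reference_motif: AAAAG
    disease_motif: AAGGG
    pathogenic_min_repeats: 400
    notes: Disease requires biallelic expansion of the mutated AAGGG motif.
  - code: DM2
    name: Myotonic dystrophy type 2 (CNBP/ZNF9)
    inheritance: AD
    contig: "3"
    start: 128891419
    end: 128891502
    reference_motif: CCTG
    disease_motif: CCTG
    normal_max_repeats: 26
    pathogenic_min_repeats: 75
    notes: Standard range <26 repeats; >=75 required for pathogenicity.
  - code: GD
    name: Glutaminase deficiency (GLS)
    inheritance: AR
    contig: "2"
    start: 191745598
    end: 191745646
    reference_motif: GCA
    disease_motif: GCA
    normal_max_repeats: 16
    pathogenic_min_repeats: 680
    notes: Controls carry 8-16 repeats; 680-1500 required to cause disease.
  - code: SCA31
    name: Spinocerebellar ataxia 31 (BEAN1)
    inheritance: AD
    contig: "16"
    start: 66524301
    end: 66524466
    reference_motif: TAAAA
    disease_motif: TGGAA
    notes: Pathogenic TGGAA insertion; repeat-count thresholds not well defined.
  - code: SCA37
    name: Spinocerebellar ataxia 37 (DAB1)
    inheritance: AD
    contig: "1"
    start: 57832715
    end: 57832790
    reference_motif: AAAAT
    disease_motif: ATTTC
    pathogenic_min_repeats: 31
    notes: Pathogenic ATTTC insertions of 31-75 repeats within the AAAAT repeat.
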