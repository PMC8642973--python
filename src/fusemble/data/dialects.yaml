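# Declarative column dialects for the seven supported fusion callers.
#
# Each section describes how one caller's tab-delimited output maps onto the
# unified call model:
#   columns               full header, in file order (writers emit all of them)
#   coordinate_convention 0-based or 1-based; parsing converts to 1-based
#   genes                 either {gene5, gene3} columns or a single {pair,
#                         separator} column such as "A--B"
#   breakpoint5/3         either {chrom, pos} columns or a {combined, format}
#                         column ("chrom:pos" or "chrom:pos:strand")
#   strands               {strand5, strand3} columns, or a single {joint}
#                         column holding both glyphs (e.g. "+-"); omitted when
#                         strands live inside a combined breakpoint
#   reads                 {total} column, or {split, spanning} columns whose
#                         sum is the evidence count; split may list several
#                         columns that are summed
#   frame                 optional column plus native-value -> internal map
#   junction_seq          optional column with breakpoint sequence
#   defaults              filler values for inert columns kept for realism

arriba:
  coordinate_convention: 1-based
  columns:
    - "#gene1"
    - "gene2"
    - "strand1"
    - "strand2"
    - "breakpoint1"
    - "breakpoint2"
    - "site1"
    - "site2"
    - "type"
    - "split_reads1"
    - "split_reads2"
    - "discordant_mates"
    - "confidence"
    - "reading_frame"
    - "fusion_transcript"
  genes: {gene5: "#gene1", gene3: "gene2"}
  breakpoint5: {combined: "breakpoint1", format: "chrom:pos"}
  breakpoint3: {combined: "breakpoint2", format: "chrom:pos"}
  strands: {strand5: "strand1", strand3: "strand2"}
  reads: {split: ["split_reads1", "split_reads2"], spanning: "discordant_mates"}
  frame:
    column: "reading_frame"
    values: {"in-frame": "in-frame", "out-of-frame": "out-of-frame", ".": "unknown"}
  junction_seq: "fusion_transcript"
  defaults: {site1: "exon", site2: "exon", type: "translocation", confidence: "high"}

cicero:
  coordinate_convention: 1-based
  columns:
    - "geneA"
    - "chrA"
    - "posA"
    - "ortA"
    - "geneB"
    - "chrB"
    - "posB"
    - "ortB"
    - "readsA"
    - "coverageA"
    - "contig"
  genes: {gene5: "geneA", gene3: "geneB"}
  breakpoint5: {chrom: "chrA", pos: "posA"}
  breakpoint3: {chrom: "chrB", pos: "posB"}
  strands: {strand5: "ortA", strand3: "ortB"}
  reads: {total: "readsA"}
  defaults: {coverageA: "0", contig: "."}

fusioncatcher:
  coordinate_convention: 1-based
  columns:
    - "Gene_1_symbol(5end_fusion_partner)"
    - "Gene_2_symbol(3end_fusion_partner)"
    - "Fusion_description"
    - "Spanning_pairs"
    - "Spanning_unique_reads"
    - "Fusion_point_for_gene_1(5end_fusion_partner)"
    - "Fusion_point_for_gene_2(3end_fusion_partner)"
    - "Predicted_effect"
    - "Fusion_sequence"
  genes:
    gene5: "Gene_1_symbol(5end_fusion_partner)"
    gene3: "Gene_2_symbol(3end_fusion_partner)"
  breakpoint5:
    combined: "Fusion_point_for_gene_1(5end_fusion_partner)"
    format: "chrom:pos:strand"
  breakpoint3:
    combined: "Fusion_point_for_gene_2(3end_fusion_partner)"
    format: "chrom:pos:strand"
  reads: {split: "Spanning_unique_reads", spanning: "Spanning_pairs"}
  frame:
    column: "Predicted_effect"
    values: {"in-frame": "in-frame", "out-of-frame": "out-of-frame", ".": "unknown"}
  junction_seq: "Fusion_sequence"
  defaults: {Fusion_description: "."}

fusionmap:
  coordinate_convention: 1-based
  columns:
    - "FusionID"
    - "SeedCount"
    - "Strand"
    - "Chromosome1"
    - "Position1"
    - "Chromosome2"
    - "Position2"
    - "KnownGene1"
    - "KnownGene2"
    - "FusionGene"
  genes: {gene5: "KnownGene1", gene3: "KnownGene2"}
  breakpoint5: {chrom: "Chromosome1", pos: "Position1"}
  breakpoint3: {chrom: "Chromosome2", pos: "Position2"}
  strands: {joint: "Strand"}
  reads: {total: "SeedCount"}
  defaults: {FusionID: "FUS_1", FusionGene: "."}

jaffa:
  coordinate_convention: 1-based
  columns:
    - "sample"
    - "fusion genes"
    - "chrom1"
    - "base1"
    - "strand1"
    - "chrom2"
    - "base2"
    - "strand2"
    - "spanning pairs"
    - "spanning reads"
    - "inframe"
    - "classification"
  genes: {pair: "fusion genes", separator: ":"}
  breakpoint5: {chrom: "chrom1", pos: "base1"}
  breakpoint3: {chrom: "chrom2", pos: "base2"}
  strands: {strand5: "strand1", strand3: "strand2"}
  reads: {split: "spanning reads", spanning: "spanning pairs"}
  frame:
    column: "inframe"
    values: {"TRUE": "in-frame", "FALSE": "out-of-frame", "NA": "unknown"}
  defaults: {sample: "sample", classification: "HighConfidence"}

mapsplice:
  coordinate_convention: 0-based
  columns:
    - "chrom_donor"
    - "doner_end"
    - "chrom_acceptor"
    - "acceptor_start"
    - "strand"
    - "coverage"
    - "annotated_gene_donor"
    - "annotated_gene_acceptor"
  genes: {gene5: "annotated_gene_donor", gene3: "annotated_gene_acceptor"}
  breakpoint5: {chrom: "chrom_donor", pos: "doner_end"}
  breakpoint3: {chrom: "chrom_acceptor", pos: "acceptor_start"}
  strands: {joint: "strand"}
  reads: {total: "coverage"}

starfusion:
  coordinate_convention: 1-based
  columns:
    - "#FusionName"
    - "JunctionReadCount"
    - "SpanningFragCount"
    - "SpliceType"
    - "LeftGene"
    - "LeftBreakpoint"
    - "RightGene"
    - "RightBreakpoint"
    - "LargeAnchorSupport"
    - "FFPM"
    - "PROT_FUSION_TYPE"
  genes: {pair: "#FusionName", separator: "--"}
  breakpoint5: {combined: "LeftBreakpoint", format: "chrom:pos:strand"}
  breakpoint3: {combined: "RightBreakpoint", format: "chrom:pos:strand"}
  reads: {split: "JunctionReadCount", spanning: "SpanningFragCount"}
  frame:
    column: "PROT_FUSION_TYPE"
    values: {"INFRAME": "in-frame", "FRAMESHIFT": "out-of-frame", ".": "unknown"}
  defaults:
    SpliceType: "ONLY_REF_SPLICE"
    LeftGene: "."
    RightGene: "."
    LargeAnchorSupport: "YES"
    FFPM: "0.0"
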