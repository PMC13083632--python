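# Toy assay-metadata data model used by the table-to-model worked examples.
# Synthetic: shaped like repository submission schemas for omics assays.
name: toy_geo
attributes:
  - name: Assay
    description: The measurement technology used to generate the data.
    values: [RNA-seq, ATAC-seq, whole genome sequencing, single-cell RNA-seq]
  - name: Species
    description: Organism from which the samples were derived.
    values: [Homo sapiens, Mus musculus, Rattus norvegicus]
  - name: LibraryPreparationMethod
    description: Library preparation kit or protocol used before sequencing.
    values: [TruSeq, Nextera XT, KAPA HyperPrep, SMART-Seq v4, Chromium 3 prime]
  - name: Tissue
    description: Tissue of origin of the sample.
    values: [kidney, liver, brain, blood, tumor]
  - name: Platform
    description: Instrument platform used for sequencing.
    values: [Illumina NovaSeq 6000, Illumina HiSeq 2500, Oxford Nanopore PromethION]
  - name: FileFormat
    description: Format of the submitted data files.
    values: [fastq, bam, vcf, csv]
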