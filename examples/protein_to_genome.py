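"""Project a protein interval (e.g. a domain hit) onto genomic CDS segments.

A domain reported in amino-acid coordinates maps to one genomic interval per
CDS segment it spans, which is what lets a structure panel shade the CDS
fragments that encode it.
"""

from genepanel.gene_structure import map_protein_interval_to_genome
from genepanel.model import FeatureSegment, GeneModel, SegmentKind

gene = GeneModel(
    gene_id="demo", transcript_id="demo.1", chrom="Chr1", strand="+",
    segments=[
        FeatureSegment(SegmentKind.CDS, 101, 160),
        FeatureSegment(SegmentKind.CDS, 261, 320),
    ],
)

# amino acids 19-22 sit on the junction between the two CDS segments
intervals = map_protein_interval_to_genome(gene, 19, 22)
print("aa 19-22 ->", intervals)
# -> [(155, 160), (261, 266)]: the last two codons of CDS 1 and the first
#    two codons of CDS 2.

minus = GeneModel(
    gene_id="rev", transcript_id="rev.1", chrom="Chr1", strand="-",
    segments=[FeatureSegment(SegmentKind.CDS, 201, 260)],
)
print("aa 1 on minus strand ->", map_protein_interval_to_genome(minus, 1, 1))
# -> [(258, 260)]: translation starts at the highest coordinates on -.
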