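criterion	section	default_points	min_points	max_points	description
1A	1	0	0	0	Contains protein-coding or other known functionally important elements
1B	1	-0.6	-0.6	-0.6	Does not contain protein-coding or any known functionally important elements
2A	2	1.0	0	1.0	Complete overlap of an established haploinsufficiency gene or genomic region
2B	2	0	0	0	Partial overlap of an established HI genomic region, unclear involvement of critical elements
2C	2	-1.0	-1.0	0	Complete overlap of an established benign CNV region
2D	2	-1.0	-1.0	0	Smaller than an established benign CNV region, breakpoints within
2E	2	0	-1.0	0.9	Both breakpoints within the same gene; case-by-case evaluation
2F	2	-1.0	-1.0	0	Completely contained within an established benign CNV region
2G	2	0	0	0	Overlaps a benign CNV region but includes additional material
2H	2	0.15	0	0.15	Two or more HI predictors suggest at least one gene in the interval is haploinsufficient
3A	3	0	0	0	0-24 protein-coding genes in the interval
3B	3	0.45	0.45	0.45	25-34 protein-coding genes in the interval
3C	3	0.9	0.9	0.9	35 or more protein-coding genes in the interval
4A	4	0.3	0	0.45	Reported proband(s) with highly specific, relatively unique phenotype consistent with the region
4B	4	0.3	0	0.45	Reported proband(s) with consistent but nonspecific phenotype
4C	4	0.15	0	0.3	Reported proband(s) with consistent phenotype of uncertain specificity
4D	4	0	0	0	Reported case with phenotype uninformative for the region
4E	4	0.1	0	0.3	Reported case with unknown phenotype
4F	4	-0.3	-0.9	0	Common population variation: overlap with CNVs in general-population controls
4L	4	-0.3	-0.45	0	Statistically robust evidence against pathogenicity
5A	5	0	0	0.45	De novo or segregation data for the patient under evaluation; case-by-case
5B	5	-0.3	-0.45	0	Inherited from an apparently unaffected parent
5C	5	-0.15	-0.3	0	Present in an apparently unaffected relative
5D	5	0	0	0.45	Segregates with a consistent phenotype in the family
5E	5	0	0	0.15	Inheritance and family phenotype information partially informative
5F	5	-0.45	-0.45	0	Phenotype inconsistent with what is expected for the region
5G	5	0	0	0	Inheritance information is unavailable or uninformative
5H	5	0	0	0.3	Inheritance unavailable; phenotype highly specific for the region
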