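# Editable cis-regulatory element catalog (PlantCARE-style consensus).
# Approximate community consensus strings; replace with project-specific
# definitions when exact binding sites are known.
name	iupac	description
MYC-motif	CANNTG	MYC recognition site (bHLH E-box); gene expression regulation, dehydration/ABA responsiveness
WUN-motif	AAATTTCCT	Wound-responsive element; linked to cell differentiation and proliferation control
G-box	CACGTG	Light-responsive bZIP/bHLH element
ABRE	ACGTGKC	Abscisic-acid responsiveness element
CAAT-box	CCAAT	Common enhancer element in promoter and enhancer regions
TATA-box	TATAWAW	Core promoter element around -30 of transcription start
W-box	TTGACC	WRKY transcription-factor binding site
MBS	CAACTG	MYB binding site involved in drought inducibility
ARE	AAACCA	Anaerobic induction element
GT1-motif	GRWAAW	Light-responsive GT1 site
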