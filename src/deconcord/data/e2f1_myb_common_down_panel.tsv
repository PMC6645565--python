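#  Curated panel: the 12 E2F1- and Myb-dependent mitotic genes reported as
#  commonly downregulated in all three endoreplicating-cell contrasts
#  (two knockdown iEC contrasts and the salivary-gland devEC contrast).
#  Columns: gene symbol <tab> annotated function.
tum	Regulation of cytokinesis
pav	Regulation of cytokinesis
sti	Regulation of cytokinesis
Nnf1a	Component of kinetochore
Kmn1	Component of kinetochore
Klp67A	Regulation of mitotic spindle assembly
mad2	Component of Spindle Assembly checkpoint
polo	Spindle assembly, Spindle assembly checkpoint, cytokinesis
msd1	Facilitates microtubule nucleation for chromosome segregation
msd5	Centrosome independent nucleation of microtubules
nod	meiotic chromosome segregation
CG7341	Unknown
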