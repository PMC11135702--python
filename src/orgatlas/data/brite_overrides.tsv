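# raw BRITE label	final category
Enzymes	unannotated-generic
Exosome	unannotated-generic
Exosomes	unannotated-generic
Chromosome and associated proteins	Information processing
Transfer RNA biogenesis	Protein synthesis
Ribosome	Protein synthesis
Ribosome biogenesis	Protein synthesis
Translation factors	Protein synthesis
Ubiquitin system	Ubiquitin system
Membrane trafficking	Membrane trafficking
Transporters	Transport
Photosynthesis proteins	Photosynthesis
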