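Autophagy
Cell Cycle
Cell-Cell communication
Cellular responses to stimuli
Chromatin organization
Circadian Clock
Developmental Biology
Disease
DNA Repair
DNA Replication
Extracellular matrix organization
Gene expression (Transcription)
Hemostasis
Immune System
Metabolism
Metabolism of proteins
Metabolism of RNA
Muscle contraction
Neuronal System
Organelle biogenesis and maintenance
Programmed Cell Death
Protein localization
Reproduction
Sensory Perception
Signal Transduction
Transport of small molecules
Vesicle-mediated transport
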