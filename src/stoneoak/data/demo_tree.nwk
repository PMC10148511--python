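((((('Lithocarpus acuminatus':0.3,'Lithocarpus corneus':0.3):0.25,('Lithocarpus konishii':0.35,'Lithocarpus glaber':0.35):0.2):0.2,(('Lithocarpus megacarpus':0.4,'Lithocarpus revolutus':0.4):0.2,'Lithocarpus hancei':0.6):0.15):0.15,((('Lithocarpus truncatus':0.3,'Lithocarpus xylocarpus':0.3):0.3,'Lithocarpus elegans':0.6):0.2,'Lithocarpus edulis':0.8):0.1):0.1,('Lithocarpus pachylepis':0.5,'Lithocarpus dealbatus':0.5):0.5);
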