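species,fruit_type,median_mat,median_zone,mean_mat,mean_zone
Lithocarpus bancanus,AC,26.2,tropical,26.2,tropical
Lithocarpus bennettii,AC,26.2,tropical,26.2,tropical
Lithocarpus blumeanus,AC,27.0,tropical,26.4,tropical
Lithocarpus brevicaudatus,AC,17.8,warm_temperate,18.7,warm_temperate
Lithocarpus calophyllus,AC,19.0,warm_temperate,19.4,subtropical
Lithocarpus cantleyanus,AC,26.5,tropical,26.3,tropical
Lithocarpus chrysocomus,AC,22.3,tropical,20.8,subtropical
Lithocarpus clementianus,AC,25.9,tropical,26.0,tropical
Lithocarpus conocarpus,AC,26.1,tropical,26.0,tropical
Lithocarpus cooperatus,AC,25.9,tropical,26.0,tropical
Lithocarpus dasystachyus,AC,25.0,tropical,25.0,tropical
Lithocarpus dealbatus,AC,23.4,tropical,21.9,subtropical
Lithocarpus echinophorus,AC,22.2,tropical,21.4,subtropical
Lithocarpus echinotholus,AC,18.6,warm_temperate,18.6,warm_temperate
Lithocarpus edulis,AC,16.1,warm_temperate,16.1,warm_temperate
Lithocarpus elegans,AC,24.4,tropical,21.7,subtropical
Lithocarpus encleisocarpus,AC,26.2,tropical,26.1,tropical
Lithocarpus ewyckii,AC,25.9,tropical,25.8,tropical
Lithocarpus fenestratus,AC,21.1,subtropical,19.6,subtropical
Lithocarpus ferrugineus,AC,25.0,tropical,25.0,tropical
Lithocarpus formosanus,AC,17.5,warm_temperate,17.5,warm_temperate
Lithocarpus gigantophyllus,AC,25.0,tropical,25.0,tropical
Lithocarpus glaber,AC,17.8,warm_temperate,18.0,warm_temperate
Lithocarpus gracilis,AC,25.9,tropical,25.8,tropical
Lithocarpus grandifolius,AC,24.4,tropical,21.7,subtropical
Lithocarpus hancei,AC,17.8,warm_temperate,18.4,warm_temperate
Lithocarpus handelianus,AC,24.1,tropical,24.1,tropical
Lithocarpus harlandii,AC,17.8,warm_temperate,18.4,warm_temperate
Lithocarpus henryi,AC,16.2,warm_temperate,15.4,warm_temperate
Lithocarpus jacobsii,AC,25.0,tropical,25.0,tropical
Lithocarpus kawakamii,AC,17.5,warm_temperate,17.5,warm_temperate
Lithocarpus konishii,AC,20.8,subtropical,20.8,subtropical
Lithocarpus leptogyne,AC,25.9,tropical,25.8,tropical
Lithocarpus licentii,AC,22.2,tropical,22.2,tropical
Lithocarpus lindleyanus,AC,27.0,tropical,26.0,tropical
Lithocarpus litseifolius,AC,21.1,subtropical,20.4,subtropical
Lithocarpus longipedicellatus,AC,22.3,tropical,19.8,subtropical
Lithocarpus lucidus,AC,26.2,tropical,26.2,tropical
Lithocarpus luteus,AC,25.0,tropical,25.0,tropical
Lithocarpus mairei,AC,14.9,warm_temperate,14.9,warm_temperate
Lithocarpus meijeri,AC,25.0,tropical,25.0,tropical
Lithocarpus naiadarum,AC,24.1,tropical,24.1,tropical
Lithocarpus nieuwenhuisii,AC,26.0,tropical,26.0,tropical
Lithocarpus pachyphyllus,AC,18.3,warm_temperate,18.3,warm_temperate
Lithocarpus rosthornii,AC,19.4,subtropical,19.3,subtropical
Lithocarpus rufovillosus,AC,16.1,warm_temperate,16.1,warm_temperate
Lithocarpus sericobalanos,AC,27.2,tropical,26.6,tropical
Lithocarpus shinsuiensis,AC,17.5,warm_temperate,17.5,warm_temperate
Lithocarpus silvicolarum,AC,21.1,subtropical,20.4,subtropical
Lithocarpus skanianus,AC,20.1,subtropical,19.9,subtropical
Lithocarpus stenopus,AC,22.2,tropical,22.2,tropical
Lithocarpus taitoensis,AC,17.8,warm_temperate,18.4,warm_temperate
Lithocarpus amygdalifolius,ER,22.2,tropical,21.2,subtropical
Lithocarpus balansae,ER,22.1,tropical,21.5,subtropical
Lithocarpus beccarianus,ER,25.0,tropical,25.0,tropical
Lithocarpus cleistocarpus,ER,17.8,warm_temperate,18.3,warm_temperate
Lithocarpus corneus,ER,18.7,warm_temperate,19.7,subtropical
Lithocarpus echinifer,ER,25.0,tropical,25.0,tropical
Lithocarpus fenzelianus,ER,24.1,tropical,24.1,tropical
Lithocarpus kalkmanii,ER,25.0,tropical,25.0,tropical
Lithocarpus lampadarius,ER,25.5,tropical,25.6,tropical
Lithocarpus laoticus,ER,17.3,warm_temperate,16.7,warm_temperate
Lithocarpus lepidocarpus,ER,17.5,warm_temperate,17.5,warm_temperate
Lithocarpus pachylepis,ER,22.2,tropical,19.8,subtropical
Lithocarpus pulcher,ER,25.0,tropical,25.0,tropical
Lithocarpus revolutus,ER,26.1,tropical,26.1,tropical
Lithocarpus ruminatus,ER,25.0,tropical,25.0,tropical
Lithocarpus truncatus,ER,22.1,tropical,20.4,subtropical
Lithocarpus turbitus,ER,25.0,tropical,25.0,tropical
Lithocarpus uvariifolius,ER,17.5,warm_temperate,18.6,warm_temperate
Lithocarpus variolosus,ER,15.7,warm_temperate,15.7,warm_temperate
Lithocarpus xylocarpus,ER,22.1,tropical,20.4,subtropical
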