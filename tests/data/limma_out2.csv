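"","logFC","t","P.Value","adj.P.Val"
"g0"," 2.97783837088522"," 3.44766030591479","0.004764125048956","0.0714618757343"
"g1"," 2.66215772514453"," 1.92453536510039","0.078095938418119","0.9270372961581"
"g2"," 3.08754627017436"," 3.63410196761510","0.003375526086825","0.0675105217365"
"g3"," 2.70336159919869"," 4.53542247333735","0.000667493419456","0.0400496051674"
"g4"," 1.81052012882689"," 3.79766804990440","0.002500181592489","0.0675105217365"
"g5"," 0.35570477036442"," 0.22964996629985","0.822196107320324","0.9961395469000"
"g6","-0.15200683279226","-0.52668710669996","0.607921503215263","0.9961395469000"
"g7","-0.54840235263317","-0.54102625284950","0.598299042000781","0.9961395469000"
"g8"," 0.10036889935976"," 0.06822975452928","0.946716151326223","0.9961395469000"
"g9","-0.33698550001766","-0.48901527232644","0.633565882141230","0.9961395469000"
"g10"," 0.20918051497458"," 0.43180202431433","0.673471783774624","0.9961395469000"
"g11","-0.32253274532971","-0.65238974660617","0.526337427109769","0.9961395469000"
"g12","-0.97205467603773","-1.34438547706730","0.203461079938950","0.9961395469000"
"g13","-0.01254592584670","-0.01950769944499","0.984753764223600","0.9961395469000"
"g14"," 1.25550829948155"," 1.52219006863789","0.153632107497628","0.9838878695019"
"g15","-1.65107434733101","-1.37483006074758","0.194083344706275","0.9961395469000"
"g16"," 0.83689959921836"," 0.66591995461229","0.517943949760367","0.9961395469000"
"g17"," 0.98692433245014"," 0.71458815773084","0.488407535932996","0.9961395469000"
"g18"," 0.39049133604340"," 0.36252880798919","0.723203743729646","0.9961395469000"
"g19"," 0.07663197147751"," 0.04786917842269","0.962600753445920","0.9961395469000"
"g20","-0.02851470751353","-0.06117647917342","0.952216526266096","0.9961395469000"
"g21"," 0.31454823334134"," 0.74961851786979","0.467794761324488","0.9961395469000"
"g22"," 0.27359672314310"," 0.28297162511815","0.781976520233992","0.9961395469000"
"g23","-0.12056519260953","-0.34482595788071","0.736138858446974","0.9961395469000"
"g24","-0.01690000225086","-0.05844682935628","0.954345902212911","0.9961395469000"
"g25","-0.79127020964743","-0.74786872652731","0.468811348409451","0.9961395469000"
"g26","-0.92728277032393","-1.05366958787039","0.312599943002069","0.9961395469000"
"g27","-2.29435826546324","-1.73482245519938","0.108121501984021","0.9270372961581"
"g28"," 0.14174826224021"," 0.14572690642067","0.886534059621284","0.9961395469000"
"g29","-0.14522855032206","-0.12303239327924","0.904099361716143","0.9961395469000"
"g30"," 0.59123237017753"," 0.75941524606960","0.462128591389564","0.9961395469000"
"g31"," 0.42216795854950"," 0.91176199130636","0.379682772926039","0.9961395469000"
"g32"," 0.01079799136027"," 0.03865192448332","0.969797668619060","0.9961395469000"
"g33","-0.47097084308349","-0.92262169684674","0.374217462026840","0.9961395469000"
"g34","-0.01502916336669","-0.01209097609380","0.990549902237962","0.9961395469000"
"g35","-0.75553958370044","-1.56832436062917","0.142547205571164","0.9838878695019"
"g36","-0.05924177716352","-0.06779275385079","0.947056858567123","0.9961395469000"
"g37","-0.00426983066647","-0.01496700841299","0.988302209368415","0.9961395469000"
"g38","-1.13232109496980","-0.95335334975310","0.359049905001189","0.9961395469000"
"g39","-0.13659941756242","-0.42773288764694","0.676351819042971","0.9961395469000"
"g40"," 0.01926001103537"," 0.04248670770367","0.966803060147374","0.9961395469000"
"g41"," 0.76873224631625"," 0.79425276818527","0.442332148293507","0.9961395469000"
"g42","-1.26399971590915","-1.20772305663421","0.250207391194727","0.9961395469000"
"g43"," 1.41983936265903"," 0.91113935480300","0.379997794319203","0.9961395469000"
"g44"," 0.58737832480540"," 0.95568090262229","0.357919116446767","0.9961395469000"
"g45","-0.00612909734603","-0.00493916799742","0.996139546899996","0.9961395469000"
"g46"," 0.64173250314745"," 1.73464241807744","0.108154351218440","0.9270372961581"
"g47","-0.27771643560466","-0.31370684179943","0.759080516209530","0.9961395469000"
"g48"," 0.32259924228651"," 0.36885341173038","0.718603775909097","0.9961395469000"
"g49","-0.02493599091584","-0.02260443136502","0.982333930100450","0.9961395469000"
"g50","-0.04865663348741","-0.06128042098879","0.952135449661887","0.9961395469000"
"g51"," 0.88543789762924"," 1.06031170890005","0.309688713269680","0.9961395469000"
"g52","-0.07464824961199","-0.23990624985768","0.814414910583219","0.9961395469000"
"g53","-0.55776533476740","-0.72619874593059","0.481514908096411","0.9961395469000"
"g54","-0.52066819848968","-0.72641285134577","0.481388366941061","0.9961395469000"
"g55"," 0.15593741283680"," 0.28601995509163","0.779695731564598","0.9961395469000"
"g56","-0.01512545157739","-0.01370389834163","0.989289350508818","0.9961395469000"
"g57","-0.98549172165100","-1.48162463978815","0.163981311583646","0.9838878695019"
"g58"," 0.33223399542159"," 0.21979036214123","0.829695009641850","0.9961395469000"
"g59","-0.80052258258598","-0.71947620138836","0.485498455039379","0.9961395469000"
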