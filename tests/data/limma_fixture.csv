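,s0,s1,s2,s3,s4,s5,s6,s7,s8,s9,s10
g0,7.304717079754432,5.960015893759504,7.750451195806457,7.940564716391214,5.048964811346163,7.697820493137682,9.127840403167285,8.683757407656419,8.98319884249571,8.14695607242642,9.87939797486283
g1,7.777791935428948,7.066030697561216,8.127241206968034,7.467509342252046,6.140707537116762,5.868750784082499,4.541117399171001,6.378450301307272,5.450074089013747,5.31513763645474,4.819070455596059
g2,8.22254133867403,6.845470517931198,6.571672177836893,6.6478664495117705,7.532309185553348,7.765444064364079,7.8127326115959885,7.830821003007883,9.541647600870462,6.993584983615385,6.887757270928463
g3,6.186227271752122,7.615979422575496,8.128972292720892,6.886052542345125,6.1598435230374715,6.1755187843087604,7.650592787824701,7.743254171203442,7.543154268305195,6.334490292711306,7.23216132306672
g4,7.116685809140728,7.218688596729013,7.87142877794819,7.223595548774682,7.6789135630718945,7.067579069488891,7.2891193986899845,7.63128822583854,5.542844180144334,6.6803287836426986,6.529627345707205
g5,6.361122151756658,6.724857748773316,8.494941311234395,6.1341688843067566,7.968278354591481,5.317130228384196,6.665114970014225,7.162753065105005,7.586222331359278,7.711226579792855,7.793347235199925
g6,6.651274927751563,6.537648207335433,7.857975881257154,6.808695675118385,5.724313676662078,5.866712785996519,6.080547713998389,7.497160744053764,7.142425736070566,7.690485354067768,6.572747353663466
g7,7.158539691076714,7.625590393967337,6.690653460279762,7.4567752375574115,6.338074058933349,6.636946153434928,6.618262106001671,5.804160354410961,7.486972480785582,6.530597659797277,7.0124941187276875
g8,7.480746658905909,7.446531176029944,7.665385108972786,6.901514515490576,6.576701687955846,6.920281789093601,5.31266556604197,5.552887527576913,5.677300387645598,6.002753172398518,7.399774226723436
g9,6.094520944639939,6.62183744596061,8.299228297786065,6.643736028938574,7.737515568467087,6.066382319990123,6.79456244213237,6.049977945089418,6.660966924099437,7.840308137457395,5.2726795768076515
g10,7.434423643545857,7.237735602332278,6.405850044303206,5.553942145611545,7.0721295077138695,6.470507290936197,7.232676211354704,7.021852145523443,8.601778891320915,6.760644372526976,5.976502507378135
g11,7.1792756349563165,7.2199966839717655,8.359187575240437,7.835111245914579,7.356871059149509,8.463302891219563,5.811236945677149,6.360248467250252,6.073424058594475,6.610190196844232,5.623313852443691
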