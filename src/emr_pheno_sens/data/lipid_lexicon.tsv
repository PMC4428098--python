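term	generic	drug_class
gemfibrozil	gemfibrozil	fibrate
Lopid	gemfibrozil	fibrate
fenofibrate	fenofibrate	fibrate
Antara	fenofibrate	fibrate
Lofibra	fenofibrate	fibrate
Tricor	fenofibrate	fibrate
Triglide	fenofibrate	fibrate
clofibrate	clofibrate	fibrate
Atromid-S	clofibrate	fibrate
niacin	niacin	niacin
cholestyramine	cholestyramine	resin
Questran	cholestyramine	resin
Questran Light	cholestyramine	resin
Prevalite	cholestyramine	resin
Locholest	cholestyramine	resin
Locholest Light	cholestyramine	resin
colestipol	colestipol	resin
Colestid	colestipol	resin
colesevelam	colesevelam	resin
WelChol	colesevelam	resin
ezetimibe	ezetimibe	cholesterol-absorption-inhibitor
Zetia	ezetimibe	cholesterol-absorption-inhibitor
atorvastatin	atorvastatin	statin
Lipitor	atorvastatin	statin
fluvastatin	fluvastatin	statin
Lescol	fluvastatin	statin
lovastatin	lovastatin	statin
Mevacor	lovastatin	statin
Altoprev	lovastatin	statin
pravastatin	pravastatin	statin
Pravachol	pravastatin	statin
rosuvastatin	rosuvastatin	statin
Crestor	rosuvastatin	statin
simvastatin	simvastatin	statin
Zocor	simvastatin	statin
Advicor	lovastatin-niacin	combination
Caduet	atorvastatin-amlodipine	combination
Vytorin	simvastatin-ezetimibe	combination
fibrate	fibrate	fibrate
fibrates	fibrate	fibrate
resin	resin	resin
resins	resin	resin
statin	statin	statin
statins	statin	statin
cholesterol absorption inhibitor	cholesterol-absorption-inhibitor	cholesterol-absorption-inhibitor
HMG CoA reductase inhibitor	statin	statin
HMG CoA reductase inhibitors	statin	statin
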