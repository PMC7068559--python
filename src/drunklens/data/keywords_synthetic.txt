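# Synthetic stand-in for a 46-entry drinking-keyword list (the published
# list is not redistributable here).  Unambiguous drinking-related keywords;
# the seed keyword "drunk" is added separately at load time for 47 total.
hangover
hungover
tailgate
vodka
wasted
sober
bar
ale
beer
wine
whiskey
tequila
rum
gin
champagne
liquor
booze
brewery
cocktail
margarita
martini
keg
shots
tipsy
buzzed
hammered
plastered
sloshed
smashed
blackout
pregame
happy hour
last call
on the rocks
mixer
chug
beer pong
flask
bartender
brew
lager
cider
sangria
mimosa
moonshine
nightcap
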