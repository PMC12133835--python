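# Neutral filler vocabulary for the synthetic-data generator.
# None of these words may appear in any verbalizer label-word list.
morning
afternoon
evening
weekend
coffee
lunch
dinner
kitchen
garden
window
street
market
train
station
bicycle
weather
raining
sunny
cloudy
meeting
project
deadline
office
email
phone
message
computer
keyboard
notebook
library
reading
cooking
recipe
grocery
shopping
walking
running
football
concert
guitar
playlist
movie
series
episode
holiday
travel
airport
ticket
luggage
mountain
river
beach
picnic
neighbor
birthday
package
delivery
laundry
cleaning
furniture
painting
plants
watering
puzzle
chess
homework
lecture
campus
printer
charger
battery
umbrella
jacket
sweater
sandwich
bakery
cheese
apple
orange
banana
tomato
pasta
noodles
breakfast
newspaper
magazine
podcast
camera
photo
album
museum
gallery
theater
schedule
calendar
appointment
parking
traffic
bridge
tunnel
elevator
staircase
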